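"""Knowledge inputs: pathway-gene associations, regulatory networks, annotation
and disease tables.

The panel-design pipeline integrates heterogeneous prior knowledge about which
genes report on which pathways.  All sources are harmonized into a single
bipartite pathway-gene association structure; the transcriptional regulatory
network is a separate, directed, gene-only graph.  Gene identifiers are plain
symbol-like strings in a single namespace — any cross-source identifier mapping
is applied by the caller (``read_gene_sets(..., id_map=...)``) before
harmonization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

ROLES = ("regulator", "target", "unspecified")


class ParseError(ValueError):
    """A knowledge input file violates its format contract."""


@dataclass(frozen=True)
class AssociationEdge:
    """One pathway-gene association with its role and provenance."""

    pathway: str
    gene: str
    role: str = "unspecified"
    provenance: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")


class PathwayGeneAssociations:
    """Bipartite pathway <-> gene association graph.

    Edges connect pathway nodes only to gene nodes.  Each edge carries a role
    (``regulator``, ``target`` or ``unspecified``) and a provenance set of
    source labels.  Duplicate (pathway, gene, role) triples merge their
    provenance; the same (pathway, gene) pair may appear with conflicting
    roles, in which case both edges are retained.
    """

    def __init__(self, edges: Iterable[AssociationEdge] = ()) -> None:
        merged: dict[tuple[str, str, str], set[str]] = {}
        for e in edges:
            merged.setdefault((e.pathway, e.gene, e.role), set()).update(e.provenance)
        self._edges = {
            key: frozenset(prov) for key, prov in merged.items()
        }
        self.pathways = frozenset(p for p, _, _ in self._edges)
        self.genes = frozenset(g for _, g, _ in self._edges)
        overlap = self.pathways & self.genes
        if overlap:
            raise ValueError(
                "pathway and gene namespaces must be disjoint (bipartite); "
                f"shared identifiers: {sorted(overlap)[:5]}"
            )

    @property
    def edges(self) -> frozenset[AssociationEdge]:
        return frozenset(
            AssociationEdge(p, g, r, prov) for (p, g, r), prov in self._edges.items()
        )

    def __len__(self) -> int:
        return len(self._edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayGeneAssociations):
            return NotImplemented
        return self._edges == other._edges

    def genes_of(self, pathway: str) -> frozenset[str]:
        return frozenset(g for p, g, _ in self._edges if p == pathway)

    def pathways_of(self, gene: str) -> frozenset[str]:
        return frozenset(p for p, g, _ in self._edges if g == gene)

    def membership(self) -> dict[str, frozenset[str]]:
        """Pathway -> member gene set (roles collapsed)."""
        out: dict[str, set[str]] = {p: set() for p in self.pathways}
        for p, g, _ in self._edges:
            out[p].add(g)
        return {p: frozenset(gs) for p, gs in out.items()}

    def gene_membership(self) -> dict[str, frozenset[str]]:
        """Gene -> set of pathways it is associated with."""
        out: dict[str, set[str]] = {g: set() for g in self.genes}
        for p, g, _ in self._edges:
            out[g].add(p)
        return {g: frozenset(ps) for g, ps in out.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pathway": p, "gene": g, "role": r, "provenance": ",".join(sorted(prov))}
            for (p, g, r), prov in sorted(self._edges.items())
        ]
        return pd.DataFrame(rows, columns=["pathway", "gene", "role", "provenance"])


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Directed gene-gene network; an edge (source, target) means the source
    gene regulates the target gene's transcription."""

    edges: frozenset[tuple[str, str, str]]  # (source, target, relation)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str] | tuple[str, str, str]],
        allow_self_loops: bool = False,
    ) -> "RegulatoryNetwork":
        edges = set()
        for row in pairs:
            src, tgt = row[0], row[1]
            rel = row[2] if len(row) > 2 else ""
            if src == tgt and not allow_self_loops:
                raise ValueError(f"self-loop {src}->{tgt} (pass allow_self_loops=True to keep)")
            edges.add((src, tgt, rel))
        return cls(frozenset(edges))

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(n for s, t, _ in self.edges for n in (s, t))

    def edge_pairs(self) -> list[tuple[str, str]]:
        return sorted({(s, t) for s, t, _ in self.edges})

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class AnnotationTable:
    """Gene -> annotation-term rows with evidence codes (GO/BP-like)."""

    frame: pd.DataFrame  # columns: gene, term, evidence

    #: evidence codes treated as experimental (GO experimental evidence branch)
    EXPERIMENTAL_CODES = frozenset(
        {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "HTP", "HDA", "HMP", "HGI", "HEP"}
    )

    def __post_init__(self) -> None:
        missing = {"gene", "term", "evidence"} - set(self.frame.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")

    def experimental_only(self) -> "AnnotationTable":
        keep = self.frame["evidence"].isin(self.EXPERIMENTAL_CODES)
        return AnnotationTable(self.frame.loc[keep].reset_index(drop=True))

    def term_to_genes(self) -> dict[str, frozenset[str]]:
        return {
            term: frozenset(sub["gene"])
            for term, sub in self.frame.groupby("term", sort=True)
        }

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.frame["gene"])

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.frame["term"])


@dataclass(frozen=True)
class DiseaseTable:
    """Deduplicated gene-disease association pairs (DisGeNet-like)."""

    frame: pd.DataFrame  # columns: gene, disease

    def __post_init__(self) -> None:
        missing = {"gene", "disease"} - set(self.frame.columns)
        if missing:
            raise ValueError(f"disease table missing columns: {sorted(missing)}")
        object.__setattr__(
            self, "frame", self.frame.drop_duplicates(["gene", "disease"]).reset_index(drop=True)
        )

    def counts_per_gene(self, genes: Sequence[str] | None = None) -> pd.Series:
        """Disease-association count per gene; genes absent from the table
        count zero when an explicit gene list is given."""
        counts = self.frame.groupby("gene")["disease"].nunique()
        if genes is None:
            return counts
        return counts.reindex(list(genes), fill_value=0).astype(int)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.frame["gene"])


# ---------------------------------------------------------------------------
# readers / writers


def _apply_id_map(gene: str, id_map: Mapping[str, str] | None) -> str:
    if id_map is None:
        return gene
    return id_map.get(gene, gene)


def read_gene_sets(
    path: str | Path,
    source_label: str | None = None,
    role: str = "unspecified",
    id_map: Mapping[str, str] | None = None,
) -> PathwayGeneAssociations:
    """Read a GMT file (name, description, member genes...) into associations.

    One pathway per line; member genes are deduplicated; every edge gets the
    given role and ``source_label`` (default: the file stem) as provenance.
    Lines with an empty gene list are skipped with a warning; lines with fewer
    than three fields raise :class:`ParseError` naming the line number.
    """
    path = Path(path)
    label = source_label if source_label is not None else path.stem
    edges: list[AssociationEdge] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0]
            members = [g for g in fields[2:] if g]
            if not members:
                logger.warning("%s:%d: pathway %r has no genes; skipped", path, lineno, name)
                continue
            for g in dict.fromkeys(members):  # dedup, keep order
                edges.append(
                    AssociationEdge(name, _apply_id_map(g, id_map), role, frozenset({label}))
                )
    return PathwayGeneAssociations(edges)


def write_gene_sets(assoc: PathwayGeneAssociations, path: str | Path) -> None:
    """Write pathway -> gene membership as GMT (roles and provenance are not
    representable in GMT and are dropped)."""
    with open(path, "w") as fh:
        for pathway, genes in sorted(assoc.membership().items()):
            fh.write("\t".join([pathway, "na", *sorted(genes)]) + "\n")


def read_edge_list(
    path: str | Path,
    allow_self_loops: bool = False,
    header: bool = False,
) -> RegulatoryNetwork:
    """Read a TSV edge list (source, target[, relation]) as a directed network."""
    path = Path(path)
    pairs: list[tuple[str, ...]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 columns, got {len(fields)}")
            if fields[0] == fields[1] and not allow_self_loops:
                raise ParseError(f"{path}:{lineno}: self-loop {fields[0]}->{fields[1]}")
            pairs.append(tuple(fields[:3]))
    return RegulatoryNetwork.from_pairs(pairs, allow_self_loops=allow_self_loops)


def write_edge_list(network: RegulatoryNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, t, rel in sorted(network.edges):
            fh.write(f"{s}\t{t}\t{rel}\n")


def read_annotation_table(path: str | Path) -> AnnotationTable:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    frame = frame.rename(columns={c: c.lower() for c in frame.columns})
    return AnnotationTable(frame[["gene", "term", "evidence"]])


def read_disease_table(path: str | Path) -> DiseaseTable:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    frame = frame.rename(columns={c: c.lower() for c in frame.columns})
    return DiseaseTable(frame[["gene", "disease"]])


def harmonize(sources: Sequence[PathwayGeneAssociations]) -> PathwayGeneAssociations:
    """Union association sources into one bipartite structure.

    Identical (pathway, gene, role) edges merge their provenance sets;
    conflicting roles for the same (pathway, gene) pair are both retained —
    the pipeline does not adjudicate between sources.  Idempotent.
    """
    edges: list[AssociationEdge] = []
    for src in sources:
        edges.extend(src.edges)
    return PathwayGeneAssociations(edges)
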