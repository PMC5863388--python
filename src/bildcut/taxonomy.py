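"""Six-rank lineages and lowest-common-ancestor label assignment."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from bildcut.classify import OutlierResult
from bildcut.errors import LookupError_, TaxonomyError

#: The six taxonomic ranks, shallowest first.
RANKS = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus")


@dataclass(frozen=True)
class Lineage:
    """An ordered, position-significant list of up to six rank labels
    (Kingdom..Genus); a truncated lineage is a prefix of a full one."""

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) > len(RANKS):
            raise TaxonomyError(
                f"lineage has {len(self.ranks)} ranks; at most {len(RANKS)} allowed"
            )
        if any(not r for r in self.ranks):
            raise TaxonomyError(
                f"lineage {self.ranks} has an empty rank label (rank skipping "
                "is not supported; only fully labelled prefixes are valid)"
            )

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        text = text.strip().rstrip(";")
        parts = tuple(p.strip() for p in text.split(";")) if text else ()
        return cls(parts)

    @property
    def depth(self) -> int:
        return len(self.ranks)

    def prefix(self, depth: int) -> tuple[str, ...]:
        return self.ranks[:depth]

    def __len__(self) -> int:
        return len(self.ranks)

    def __iter__(self):
        return iter(self.ranks)

    def __getitem__(self, i):
        return self.ranks[i]

    def __str__(self) -> str:
        return ";".join(self.ranks)


@dataclass(frozen=True)
class Assignment:
    """Taxonomic label assigned to one query; depth 0 means unclassified."""

    query_id: str
    lineage: Lineage
    depth: int
    n_outliers: int

    @property
    def status(self) -> str:
        return "classified" if self.depth > 0 else "unclassified"


def parse_taxonomy_table(stream: Iterable[str]) -> dict[str, Lineage]:
    """Parse a two-column TSV: sequence id, semicolon-separated lineage.

    A repeated id with an identical lineage is deduplicated silently;
    conflicting lineages for one id raise :class:`TaxonomyError`."""
    taxmap: dict[str, Lineage] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise TaxonomyError(
                f"line {lineno}: expected 2 tab-separated columns, got {len(parts)}"
            )
        seq_id, lineage_text = parts
        try:
            lineage = Lineage.from_string(lineage_text)
        except TaxonomyError as exc:
            raise TaxonomyError(f"line {lineno}: {exc}") from exc
        if seq_id in taxmap and taxmap[seq_id] != lineage:
            raise TaxonomyError(
                f"line {lineno}: id {seq_id!r} repeated with conflicting lineage"
            )
        taxmap[seq_id] = lineage
    return taxmap


def lca(lineages: Sequence[Lineage]) -> Lineage:
    """Lowest common ancestor: the longest common prefix of the rank lists.

    Labels compare by exact, case-sensitive string match per rank.  May
    be empty (depth 0) when the lineages disagree at Kingdom."""
    if not lineages:
        raise TaxonomyError("lca of an empty lineage list is undefined")
    common: list[str] = []
    for labels in zip(*(lin.ranks for lin in lineages)):
        if all(lab == labels[0] for lab in labels[1:]):
            common.append(labels[0])
        else:
            break
    return Lineage(tuple(common))


def assign(result: OutlierResult, taxmap: Mapping[str, Lineage]) -> Assignment:
    """Assign the LCA of the outliers' lineages; unclassified maps to depth 0.

    Raises :class:`LookupError_` naming the first outlier id absent from
    the taxonomy table."""
    if not result.classified:
        return Assignment(
            query_id=result.query_id, lineage=Lineage(()), depth=0, n_outliers=0
        )
    lineages = []
    for sid in result.outlier_ids:
        if sid not in taxmap:
            raise LookupError_(
                f"query {result.query_id}: outlier {sid!r} missing from the "
                "taxonomy table"
            )
        lineages.append(taxmap[sid])
    ancestor = lca(lineages)
    return Assignment(
        query_id=result.query_id,
        lineage=ancestor,
        depth=ancestor.depth,
        n_outliers=len(result.outlier_ids),
    )
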