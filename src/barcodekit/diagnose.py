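"""Diagnostic-SNP calling for a candidate new variety.

A site is diagnostic for a query individual when the query's unambiguous
base is absent from every conspecific reference sequence at that column —
the single-site signature that distinguishes a new variety from the typical
population of its species.  Each called site is annotated with the
genus-wide allele picture: which other species' consensus base matches the
query's state (shared alleles at high taxonomic distance are informative
about the variant's origin; a fully private state is the strongest call).

Sites are reported in both frames: the trimmed-alignment column and the
original reference coordinate recovered through ``column_map``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignio import Alignment

_ACGT = ("A", "C", "G", "T")


@dataclass
class AlleleTable:
    """Per-species base counts at one alignment column (1-based)."""

    site: int
    reference_site: int
    counts: dict[str, dict[str, int]]
    missing: dict[str, int]  # rows with N / ambiguity codes, per species

    @property
    def bases_observed(self) -> set[str]:
        return {b for per in self.counts.values() for b in per}

    def consensus(self, species: str) -> str | None:
        """Strict-majority base of a species at this site; None on a tie or
        when the species has no unambiguous observation."""
        per = self.counts.get(species, {})
        if not per:
            return None
        best = max(per.values())
        winners = [b for b, c in per.items() if c == best]
        return winners[0] if len(winners) == 1 else None

    def to_tsv(self) -> str:
        lines = ["site\treference_site\tspecies\tA\tC\tG\tT\tmissing"]
        for sp in sorted(set(self.counts) | set(self.missing)):
            per = self.counts.get(sp, {})
            cells = "\t".join(str(per.get(b, 0)) for b in _ACGT)
            lines.append(
                f"{self.site}\t{self.reference_site}\t{sp}\t{cells}\t"
                f"{self.missing.get(sp, 0)}"
            )
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class DiagnosticSite:
    site: int  # 1-based trimmed-alignment column
    reference_site: int  # same column in original reference coordinates
    query_state: str
    conspecific_states: frozenset[str]
    sharing_species: tuple[str, ...]  # species whose consensus == query_state
    is_private: bool

    def __post_init__(self):
        if self.query_state in self.conspecific_states:
            raise ValueError("query state cannot be among conspecific states")


def site_allele_table(
    alignment: Alignment, labels: dict[str, str], site: int
) -> AlleleTable:
    """Tabulate per-species allele counts at one alignment column.

    ``N`` and ambiguity codes are excluded from the counts and tallied as
    missing observations instead.
    """
    if not alignment.trimmed:
        raise ValueError("site_allele_table requires a trimmed alignment")
    if not (1 <= site <= alignment.width):
        raise ValueError(f"site {site} outside [1, {alignment.width}]")
    counts: dict[str, dict[str, int]] = {}
    missing: dict[str, int] = {}
    for rid in alignment.ids:
        sp = labels[rid]
        base = alignment.rows[rid][site - 1]
        if base in _ACGT:
            counts.setdefault(sp, {})
            counts[sp][base] = counts[sp].get(base, 0) + 1
        else:
            missing[sp] = missing.get(sp, 0) + 1
        missing.setdefault(sp, missing.get(sp, 0))
    return AlleleTable(
        site=site,
        reference_site=alignment.column_map[site - 1],
        counts=counts,
        missing=missing,
    )


def call_diagnostic_sites(
    alignment: Alignment,
    labels: dict[str, str],
    query_id: str,
    min_conspecific: int = 3,
) -> list[DiagnosticSite]:
    """All columns where the query's base is absent from its conspecific
    references.

    Only unambiguous query bases can be diagnostic (an ambiguity code cannot
    exclude a shared allele), and a column is only assessable when at least
    one conspecific reference shows an unambiguous base there.  Sharing
    species are those whose strict-majority consensus equals the query state;
    consensus ties disqualify a species from the sharing list.  Output is
    sorted by site and invariant to row order.
    """
    if not alignment.trimmed:
        raise ValueError("call_diagnostic_sites requires a trimmed alignment")
    if query_id not in alignment.rows:
        raise ValueError(f"query {query_id!r} not in the alignment")
    q_species = labels[query_id]
    conspecific = [
        rid
        for rid in alignment.ids
        if rid != query_id and labels[rid] == q_species
    ]
    if len(conspecific) < min_conspecific:
        raise ValueError(
            f"only {len(conspecific)} conspecific references for "
            f"{q_species!r}; need at least {min_conspecific}"
        )
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    q = np.frombuffer(alignment.rows[query_id].encode(), dtype=np.uint8)
    ref_rows = np.vstack(
        [
            np.frombuffer(alignment.rows[r].encode(), dtype=np.uint8)
            for r in conspecific
        ]
    )
    q_ok = np.isin(q, acgt)
    ref_ok = np.isin(ref_rows, acgt)
    seen = ref_ok.any(axis=0)  # column assessable at all
    matches = (ref_rows == q[None, :]) & ref_ok
    candidate = q_ok & seen & ~matches.any(axis=0)
    sites: list[DiagnosticSite] = []
    for col in np.flatnonzero(candidate):
        site = int(col) + 1
        table = site_allele_table(alignment, labels, site)
        # the query's own observation must not count toward sharing species
        q_base = chr(q[col])
        own = dict(table.counts.get(q_species, {}))
        if own.get(q_base):
            own[q_base] -= 1
            if own[q_base] == 0:
                del own[q_base]
            table.counts[q_species] = own
        states = frozenset(
            chr(c) for c in np.unique(ref_rows[:, col][ref_ok[:, col]])
        )
        sharing = tuple(
            sp
            for sp in sorted(table.counts)
            if sp != q_species and table.consensus(sp) == q_base
        )
        sites.append(
            DiagnosticSite(
                site=site,
                reference_site=alignment.column_map[col],
                query_state=q_base,
                conspecific_states=states,
                sharing_species=sharing,
                is_private=not sharing,
            )
        )
    return sites


def sites_to_tsv(sites: list[DiagnosticSite]) -> str:
    lines = [
        "site\treference_site\tquery_state\tconspecific_states\t"
        "sharing_species\tis_private"
    ]
    for s in sites:
        lines.append(
            f"{s.site}\t{s.reference_site}\t{s.query_state}\t"
            f"{','.join(sorted(s.conspecific_states))}\t"
            f"{','.join(s.sharing_species)}\t{s.is_private}"
        )
    return "\n".join(lines) + "\n"
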