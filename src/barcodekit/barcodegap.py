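"""SNP% distances and the barcode-gap verdict.

The distance between two gap-free aligned rows is SNP%: 100 x mismatches /
comparable sites, a comparable site being a column where both rows hold an
unambiguous A/C/G/T (``N`` and IUPAC ambiguity codes are missing data, never
mismatches).  A locus is judged a usable barcode when the resampled
interspecific SNP% sample is significantly larger than the pooled
intraspecific sample — the classic barcode gap, tested with a Welch t-test
plus an explicit direction gate.

The interspecific sample follows a with-replacement scheme: draw ``k_species``
species, then for each of ``k_draws`` rounds draw one representative per
species (with replacement) and record all cross-species pairwise SNP%
values, so the sample size is ``k_draws * C(k_species, 2)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alignio import Alignment, alignment_from_seqset, trim_and_degap
from . import simdata

_ACGT = frozenset(b"ACGT")


def snp_percent(row_a: str, row_b: str) -> tuple[float, int]:
    """SNP% and comparable-site count for two equal-length gap-free rows.

    Returns ``(nan, 0)`` when no site is comparable; callers must treat that
    as missing, not as zero distance.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    if "-" in row_a or "-" in row_b:
        raise ValueError("rows must be gap-free (trim the alignment first)")
    a = np.frombuffer(row_a.encode(), dtype=np.uint8)
    b = np.frombuffer(row_b.encode(), dtype=np.uint8)
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    comp = np.isin(a, acgt) & np.isin(b, acgt)
    n_comp = int(comp.sum())
    if n_comp == 0:
        return float("nan"), 0
    mism = int(((a != b) & comp).sum())
    return 100.0 * mism / n_comp, n_comp


@dataclass
class DistanceMatrix:
    """Symmetric pairwise SNP% matrix with comparable-site counts.

    Missing entries (zero comparable sites) are NaN in ``snp_percent`` and 0
    in ``comparable_sites``.
    """

    ids: list[str]
    snp_percent: np.ndarray
    comparable_sites: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        if self.snp_percent.shape != (n, n) or self.comparable_sites.shape != (n, n):
            raise ValueError("matrix shapes must match the id count")

    def value(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.snp_percent[i, j])

    def has_missing(self) -> bool:
        n = len(self.ids)
        off = ~np.eye(n, dtype=bool)
        return bool(np.isnan(self.snp_percent[off]).any())

    def to_tsv(self) -> str:
        lines = ["\t".join([""] + self.ids)]
        for i, rid in enumerate(self.ids):
            vals = [
                "NA" if math.isnan(v) else f"{v:.6f}" for v in self.snp_percent[i]
            ]
            lines.append("\t".join([rid] + vals))
        return "\n".join(lines) + "\n"


def distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """All-pairs SNP% on a trimmed alignment (vectorized column walk)."""
    if not alignment.trimmed:
        raise ValueError("distance_matrix requires a trimmed, gap-free alignment")
    mat = alignment.matrix()
    comp = alignment.comparable_mask()
    both = comp[:, None, :] & comp[None, :, :]
    n_comp = both.sum(axis=2)
    mism = ((mat[:, None, :] != mat[None, :, :]) & both).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_comp > 0, 100.0 * mism / np.maximum(n_comp, 1), np.nan)
    np.fill_diagonal(pct, 0.0)
    return DistanceMatrix(
        ids=list(alignment.ids),
        snp_percent=pct,
        comparable_sites=n_comp.astype(int),
    )


@dataclass
class DistanceSample:
    kind: str  # "intraspecific" | "interspecific"
    values: list[float]
    provenance: list[tuple]

    def __post_init__(self):
        if len(self.values) != len(self.provenance):
            raise ValueError("provenance must be parallel to values")
        if any(not (0.0 <= v <= 100.0) for v in self.values):
            raise ValueError("SNP% values must lie in [0, 100]")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values else float("nan")


def intraspecific_distances(
    matrix: DistanceMatrix, labels: dict[str, str]
) -> dict[str, DistanceSample]:
    """All unordered conspecific pairs' SNP%, per species.

    Species with fewer than two records are omitted; at least one species
    must have two.
    """
    by_species: dict[str, list[str]] = {}
    for rid in matrix.ids:
        by_species.setdefault(labels[rid], []).append(rid)
    out: dict[str, DistanceSample] = {}
    for sp in sorted(by_species):
        members = by_species[sp]
        if len(members) < 2:
            continue
        values, prov = [], []
        for a, b in itertools.combinations(members, 2):
            v = matrix.value(a, b)
            if math.isnan(v):
                raise ValueError(f"missing distance between {a!r} and {b!r}")
            values.append(v)
            prov.append((a, b))
        out[sp] = DistanceSample("intraspecific", values, prov)
    if not out:
        raise ValueError("no species has at least two records")
    return out


def pool_intraspecific(samples: dict[str, DistanceSample]) -> DistanceSample:
    values, prov = [], []
    for sp in sorted(samples):
        values.extend(samples[sp].values)
        prov.extend(samples[sp].provenance)
    return DistanceSample("intraspecific", values, prov)


def interspecific_resample(
    matrix: DistanceMatrix,
    labels: dict[str, str],
    k_species: int = 6,
    k_draws: int = 6,
    seed: int = 0,
) -> DistanceSample:
    """Resampled interspecific SNP% sample.

    ``k_species`` species are drawn without replacement; in each of
    ``k_draws`` rounds one sequence is drawn with replacement per selected
    species and every cross-species pair among the representatives
    contributes one value.
    """
    if k_species < 2:
        raise ValueError("k_species must be at least 2")
    species = sorted(set(labels[rid] for rid in matrix.ids))
    if len(species) < 2:
        raise ValueError("need at least 2 species for interspecific distances")
    if k_species > len(species):
        raise ValueError(
            f"k_species={k_species} exceeds the {len(species)} species present"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(species, size=k_species, replace=False).tolist())
    members = {
        sp: [rid for rid in matrix.ids if labels[rid] == sp] for sp in chosen
    }
    values, prov = [], []
    for rnd in range(k_draws):
        reps = {sp: members[sp][rng.integers(len(members[sp]))] for sp in chosen}
        for sp_a, sp_b in itertools.combinations(chosen, 2):
            v = matrix.value(reps[sp_a], reps[sp_b])
            if math.isnan(v):
                raise ValueError(
                    f"missing distance between {reps[sp_a]!r} and {reps[sp_b]!r}"
                )
            values.append(v)
            prov.append((sp_a, sp_b, rnd))
    return DistanceSample("interspecific", values, prov)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    sidedness: str = "two-sided"


def welch_t(
    sample_a, sample_b, sidedness: str = "two-sided"
) -> TestResult:
    """Welch unequal-variance t-test.

    ``t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b)`` with the
    Welch–Satterthwaite degrees of freedom.  Degenerate convention when both
    variances are zero: equal means -> p = 1, unequal means -> p = 0.
    ``sidedness="greater"`` tests mean_a > mean_b.
    """
    if sidedness not in ("two-sided", "greater"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    a = np.asarray(getattr(sample_a, "values", sample_a), dtype=float)
    b = np.asarray(getattr(sample_b, "values", sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return TestResult(0.0, float(a.size + b.size - 2), 1.0, sidedness)
        stat = math.copysign(math.inf, diff)
        p = 0.0 if (sidedness == "two-sided" or diff > 0) else 1.0
        return TestResult(stat, float(a.size + b.size - 2), p, sidedness)
    sa, sb = va / a.size, vb / b.size
    stat = diff / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (
        sa**2 / (a.size - 1) + sb**2 / (b.size - 1)
    )
    if sidedness == "two-sided":
        p = 2.0 * stats.t.sf(abs(stat), df)
    else:
        p = stats.t.sf(stat, df)
    return TestResult(float(stat), float(df), float(p), sidedness)


@dataclass(frozen=True)
class BarcodeVerdict:
    """Suitability call for one barcode locus.

    ``suitable`` holds iff the test rejects at ``alpha`` AND the mean
    interspecific distance exceeds the mean intraspecific distance.
    """

    barcode_name: str
    mean_intra: float
    mean_inter: float
    n_intra: int
    n_inter: int
    test: TestResult
    alpha: float
    suitable: bool

    def to_tsv(self) -> str:
        head = (
            "barcode\tmean_intra\tmean_inter\tn_intra\tn_inter\t"
            "t_statistic\tdf\tp_value\tsidedness\talpha\tsuitable\n"
        )
        return head + (
            f"{self.barcode_name}\t{self.mean_intra:.6f}\t{self.mean_inter:.6f}\t"
            f"{self.n_intra}\t{self.n_inter}\t{self.test.statistic:.6f}\t"
            f"{self.test.degrees_of_freedom:.6f}\t{self.test.p_value:.6g}\t"
            f"{self.test.sidedness}\t{self.alpha}\t{self.suitable}\n"
        )


def evaluate_barcode(
    intra: DistanceSample,
    inter: DistanceSample,
    alpha: float = 0.05,
    barcode_name: str = "barcode",
) -> BarcodeVerdict:
    """Barcode-gap verdict: two-sided Welch test plus the direction gate."""
    if not intra.values or not inter.values:
        raise ValueError("both distance samples must be non-empty")
    test = welch_t(inter, intra, sidedness="two-sided")
    mean_intra, mean_inter = intra.mean, inter.mean
    suitable = (test.p_value < alpha) and (mean_inter > mean_intra)
    return BarcodeVerdict(
        barcode_name=barcode_name,
        mean_intra=mean_intra,
        mean_inter=mean_inter,
        n_intra=len(intra.values),
        n_inter=len(inter.values),
        test=test,
        alpha=alpha,
        suitable=suitable,
    )


def gap_trial(
    n_species: int = 6,
    seqs_per_species: int = 4,
    seq_length: int = 1200,
    intra_divergence: float = 0.005,
    inter_divergence: float = 0.03,
    alpha: float = 0.05,
    k_species: int = 6,
    k_draws: int = 6,
    seed: int = 0,
) -> BarcodeVerdict:
    """One simulate -> distances -> verdict replicate.

    Convenience driver for calibration and power studies; the simulated set
    is indel-free so the alignment step is the identity.
    """
    cfg = simdata.SimConfig(
        n_species=n_species,
        seqs_per_species=seqs_per_species,
        seq_length=seq_length,
        inter_divergence=inter_divergence,
        intra_divergence=intra_divergence,
        seed=seed,
    )
    seqset, _ = simdata.simulate_genus(cfg)
    aln = trim_and_degap(alignment_from_seqset(seqset))
    dm = distance_matrix(aln)
    labels = seqset.species_map
    intra = pool_intraspecific(intraspecific_distances(dm, labels))
    inter = interspecific_resample(
        dm, labels, k_species=k_species, k_draws=k_draws, seed=seed
    )
    return evaluate_barcode(intra, inter, alpha=alpha)


def sample_to_tsv(sample: DistanceSample) -> str:
    lines = ["kind\tvalue\tprovenance"]
    for v, p in zip(sample.values, sample.provenance):
        lines.append(f"{sample.kind}\t{v:.6f}\t{':'.join(str(x) for x in p)}")
    return "\n".join(lines) + "\n"
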