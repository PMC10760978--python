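"""Synthetic genera of barcode-like sequences with known ground truth.

The generator emulates a genus-wide collection of one barcode locus: a
single genus root sequence, species roots derived from it by i.i.d.
per-site substitution, and individuals derived from their species root the
same way.  Substitution is equal-rate to a uniformly chosen different base
(Jukes–Cantor-like), applied once per lineage step.

Divergence parameters are *pairwise* expected substitution loads:
``intra_divergence`` is the expected substitutions per site separating two
conspecific individuals (so each individual carries ``intra/2`` from its
species root), and ``inter_divergence`` the expected substitutions per site
separating two heterospecific individuals (so each species root carries
``(inter - intra)/2`` from the genus root).  Equal divergences therefore
make every sequence exchangeable — a true no-gap null — while
``inter > intra`` plants a barcode gap of known size.

Composing independent equal-rate steps stays within the same kernel family,
giving a closed-form expected *observed* Hamming divergence between any two
sequences: ``D = (3/4) * (1 - prod_i(1 - 4 p_i / 3))`` over the step rates
``p_i`` on the path connecting them (``expected_observed_divergence``).

No indels are simulated — downstream analysis runs on gap-stripped
alignments — so a simulated set is equal-length and alignment-free by
construction; ``degrade_termini`` adds the unreliable read ends real Sanger
data shows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .alignio import LabeledSequenceSet, SeqRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MAX_DIVERGENCE = 0.75  # saturation bound of the equal-rate model


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic genus.

    ``intra_divergence`` is the expected pairwise substitution load between
    conspecific individuals, ``inter_divergence`` the load between
    heterospecific individuals; both lie in [0, 0.75) and
    ``inter >= intra`` (equality gives the exchangeable no-gap null).
    ``seqs_per_species`` may be a single int or a per-species list.
    Identical configs (including ``seed``) give byte-identical output.
    """

    n_species: int
    seqs_per_species: int | tuple[int, ...] = 4
    seq_length: int = 1200
    inter_divergence: float = 0.03
    intra_divergence: float = 0.005
    seed: int = 0
    terminal_noise_max: int = 0

    def __post_init__(self):
        if self.n_species < 1:
            raise ValueError("n_species must be a positive integer")
        if self.seq_length < 1:
            raise ValueError("seq_length must be a positive integer")
        counts = self.per_species_counts()
        if len(counts) != self.n_species or any(c < 1 for c in counts):
            raise ValueError("seqs_per_species must be positive for every species")
        for name in ("inter_divergence", "intra_divergence"):
            v = getattr(self, name)
            if not (0.0 <= v < _MAX_DIVERGENCE):
                raise ValueError(
                    f"{name} must lie in [0, {_MAX_DIVERGENCE}); got {v}"
                )
        if self.inter_divergence < self.intra_divergence:
            raise ValueError(
                "inter_divergence must be >= intra_divergence "
                f"(got {self.inter_divergence} < {self.intra_divergence})"
            )
        if self.terminal_noise_max < 0:
            raise ValueError("terminal_noise_max must be non-negative")

    @property
    def individual_step_rate(self) -> float:
        """Per-lineage substitution rate species root -> individual."""
        return self.intra_divergence / 2.0

    @property
    def species_step_rate(self) -> float:
        """Per-lineage substitution rate genus root -> species root."""
        return (self.inter_divergence - self.intra_divergence) / 2.0

    def per_species_counts(self) -> tuple[int, ...]:
        if isinstance(self.seqs_per_species, int):
            return (self.seqs_per_species,) * self.n_species
        return tuple(self.seqs_per_species)


@dataclass
class SimTruth:
    """Ground truth of a simulated genus, for recovery tests."""

    genus_root: str
    species_root_sequences: dict[str, str]
    pairwise_expected_divergence: dict[tuple[str, str], float]
    planted_variant: tuple[str, int, str, str] | None = None  # id, site, anc, var

    def __post_init__(self):
        if self.planted_variant is not None:
            _, site, anc, var = self.planted_variant
            length = len(self.genus_root)
            if not (1 <= site <= length):
                raise ValueError(f"planted site {site} outside [1, {length}]")
            if anc == var:
                raise ValueError("variant base must differ from the ancestral base")


def expected_observed_divergence(step_rates) -> float:
    """Expected observed Hamming fraction between the two ends of a chain of
    independent equal-rate substitution steps (identity-by-chance
    corrected): ``(3/4) * (1 - prod(1 - 4 p / 3))``."""
    prod = 1.0
    for p in step_rates:
        prod *= 1.0 - 4.0 * p / 3.0
    return 0.75 * (1.0 - prod)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with probability ``rate`` to a
    uniformly chosen different base."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < rate)
    if hit.size:
        idx = np.searchsorted(_BASES, out[hit])
        shift = rng.integers(1, 4, size=hit.size)
        out[hit] = _BASES[(idx + shift) % 4]
    return out


def _decode(seq: np.ndarray) -> str:
    return seq.tobytes().decode()


def simulate_genus(config: SimConfig) -> tuple[LabeledSequenceSet, SimTruth]:
    """Draw one synthetic genus: genus root -> species roots -> individuals.

    Headers follow the ``species|individual`` grammar (``sp01|i1`` ...).
    """
    rng = np.random.default_rng(config.seed)
    root = rng.choice(_BASES, size=config.seq_length)
    counts = config.per_species_counts()
    width = max(2, len(str(config.n_species)))
    species_names = [f"sp{k + 1:0{width}d}" for k in range(config.n_species)]
    q, r = config.species_step_rate, config.individual_step_rate
    roots: dict[str, str] = {}
    records: list[SeqRecord] = []
    for sp, n_ind in zip(species_names, counts):
        sp_root = _mutate(root, q, rng)
        roots[sp] = _decode(sp_root)
        for i in range(n_ind):
            ind = _mutate(sp_root, r, rng)
            records.append(
                SeqRecord(id=f"{sp}|i{i + 1}", species=sp, sequence=_decode(ind))
            )
    exp = expected_observed_divergence([q, q])
    pairwise = {
        (a, b): exp
        for i, a in enumerate(species_names)
        for b in species_names[i + 1 :]
    }
    seqset = LabeledSequenceSet(records)
    if config.terminal_noise_max:
        seqset = degrade_termini(
            seqset, config.terminal_noise_max, seed=config.seed + 1
        )
    truth = SimTruth(
        genus_root=_decode(root),
        species_root_sequences=roots,
        pairwise_expected_divergence=pairwise,
    )
    return seqset, truth


def simulate_clade_genus(
    config: SimConfig,
    clade_size: int,
    clade_divergence: float,
) -> tuple[LabeledSequenceSet, SimTruth, list[str]]:
    """Genus with one divergent clade: the last ``clade_size`` species derive
    from a clade ancestor that sits ``clade_divergence`` substitutions per
    site away from the genus root (a two-level star, still i.i.d. per-site).

    Returns the sequence set, truth, and the clade's species names.
    """
    if not (1 <= clade_size < config.n_species):
        raise ValueError("clade_size must be in [1, n_species)")
    if not (0.0 <= clade_divergence < _MAX_DIVERGENCE):
        raise ValueError(f"clade_divergence must lie in [0, {_MAX_DIVERGENCE})")
    rng = np.random.default_rng(config.seed)
    root = rng.choice(_BASES, size=config.seq_length)
    clade_root = _mutate(root, clade_divergence, rng)
    counts = config.per_species_counts()
    width = max(2, len(str(config.n_species)))
    species_names = [f"sp{k + 1:0{width}d}" for k in range(config.n_species)]
    clade_species = species_names[config.n_species - clade_size :]
    q, r = config.species_step_rate, config.individual_step_rate
    roots: dict[str, str] = {}
    records: list[SeqRecord] = []
    for sp, n_ind in zip(species_names, counts):
        ancestor = clade_root if sp in clade_species else root
        sp_root = _mutate(ancestor, q, rng)
        roots[sp] = _decode(sp_root)
        for i in range(n_ind):
            ind = _mutate(sp_root, r, rng)
            records.append(
                SeqRecord(id=f"{sp}|i{i + 1}", species=sp, sequence=_decode(ind))
            )
    truth = SimTruth(
        genus_root=_decode(root),
        species_root_sequences=roots,
        pairwise_expected_divergence={},
    )
    return LabeledSequenceSet(records), truth, clade_species


def plant_variant(
    seqset: LabeledSequenceSet,
    truth: SimTruth,
    record_id: str,
    site: int,
    variant_base: str,
) -> tuple[LabeledSequenceSet, SimTruth]:
    """Introduce a single fixed substitution in one record (1-based ``site``).

    Models the discovery scenario of a candidate new variety: one individual
    carrying one unambiguous base absent from its conspecific references.
    Rejects a variant equal to the current base — a silent no-op would
    corrupt recovery tests.
    """
    rec = seqset.get(record_id)
    if not (1 <= site <= len(rec.sequence)):
        raise ValueError(f"site {site} outside [1, {len(rec.sequence)}]")
    if variant_base not in "ACGT":
        raise ValueError(f"variant base must be one of A/C/G/T, got {variant_base!r}")
    current = rec.sequence[site - 1]
    if variant_base == current:
        raise ValueError(
            f"variant base {variant_base!r} equals the current base at site {site}"
        )
    new_seq = rec.sequence[: site - 1] + variant_base + rec.sequence[site:]
    records = [
        replace(r, sequence=new_seq) if r.id == record_id else r for r in seqset
    ]
    new_truth = SimTruth(
        genus_root=truth.genus_root,
        species_root_sequences=dict(truth.species_root_sequences),
        pairwise_expected_divergence=dict(truth.pairwise_expected_divergence),
        planted_variant=(record_id, site, current, variant_base),
    )
    return LabeledSequenceSet(records), new_truth


def degrade_termini(
    seqset: LabeledSequenceSet, max_len: int, seed: int = 0
) -> LabeledSequenceSet:
    """Replace a random prefix and suffix (each of length <= ``max_len``) of
    every record with random bases or ``N`` — the unreliable, primer-adjacent
    ends of Sanger reads.  The interior is untouched."""
    if max_len < 0:
        raise ValueError("max_len must be non-negative")
    if max_len == 0:
        return seqset
    min_len = min(len(r.sequence) for r in seqset)
    if max_len >= min_len / 2:
        raise ValueError(
            f"max_len {max_len} reaches half the shortest sequence ({min_len})"
        )
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGTN", dtype=np.uint8)
    records = []
    for rec in seqset:
        L = len(rec.sequence)
        pre = int(rng.integers(0, max_len + 1))
        suf = int(rng.integers(0, max_len + 1))
        arr = np.frombuffer(rec.sequence.encode(), dtype=np.uint8).copy()
        if pre:
            arr[:pre] = rng.choice(alphabet, size=pre)
        if suf:
            arr[L - suf :] = rng.choice(alphabet, size=suf)
        records.append(replace(rec, sequence=arr.tobytes().decode()))
    return LabeledSequenceSet(records)


def write_truth(truth: SimTruth, tsv_path, roots_fasta_path) -> None:
    """Serialize ground truth: variant sidecar TSV plus root-sequence FASTA."""
    with open(tsv_path, "w") as fh:
        fh.write("record_id\tsite\tancestral\tvariant\n")
        if truth.planted_variant is not None:
            rid, site, anc, var = truth.planted_variant
            fh.write(f"{rid}\t{site}\t{anc}\t{var}\n")
    with open(roots_fasta_path, "w") as fh:
        fh.write(f">genus_root\n{truth.genus_root}\n")
        for sp in sorted(truth.species_root_sequences):
            fh.write(f">{sp}\n{truth.species_root_sequences[sp]}\n")
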