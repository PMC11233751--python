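"""Synthetic references, reads, plastome pairs and cohorts — with truth.

Everything downstream of sequencing is testable against this module: it
emulates a polyploid individual whose nrDNA repeats carry several ITS2
haplotypes at skewed frequencies, paired 2x150 bp shotgun reads with
substitution errors, a pair of plastome types ~0.3% diverged with planted
indels in intergenic spacers, and cohorts mixing parental and hybrid
individuals. Every generator records exactly what it planted.

Determinism: identical spec + seed give byte-identical outputs. All
randomness flows from ``SimulationSpec.seed`` through fixed stream indices,
so adding a consumer never perturbs existing draws.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import _dna
from .errors import SpecError
from .io import Feature, ReadBatch, SequenceRecord
from .its2 import HaplotypeCatalog, ITS2Window, locate_window

__all__ = [
    "SimulationSpec",
    "ReadSimTruth",
    "PlastomePairTruth",
    "CohortSample",
    "CohortResult",
    "make_nrdna_reference",
    "make_haplotypes",
    "simulate_reads",
    "make_plastome_pair",
    "simulate_cohort",
    "COHORT_HAPLOTYPE_NAMES",
    "STATUS_MIXTURES",
]

_STREAM_NRDNA = 11
_STREAM_HAPLOTYPES = 23
_STREAM_READS = 37
_STREAM_PLASTOME = 53
_STREAM_COHORT = 71

_CHUNK_FRAGMENTS = 100_000


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for the generator.

    Defaults mirror the motivating system: a ~5,868 bp nrDNA unit with a
    133 bp ITS2 window, 2x150 bp reads, ~1000 window-spanning reads per
    library, a dominant haplotype near 88%, and plastome types diverged at
    ~0.3% with indel length differences concentrated in intergenic spacers.
    """

    seed: int = 0
    # nrDNA / ITS2
    reference_length: int = 5868
    its2_length: int = 133
    flank_length: int = 30
    anchor_length: int = 8
    n_haplotypes: int = 3
    substitutions_per_haplotype: int = 2
    mixture: tuple[float, ...] = (0.88, 0.10, 0.02)
    # reads
    n_spanning_reads_target: int = 1000
    read_length: int = 150
    per_base_error: float = 0.0
    insert_range: tuple[int, int] = (250, 450)
    base_quality: int = 30
    # plastomes
    plastome_length: int = 159320
    plastome_snp_rate: float = 0.003
    planted_indels: tuple[tuple[str, int], ...] = (
        ("rpl20-rps12", 30),
        ("rpl33-rps18", 12),
    )

    def __post_init__(self) -> None:
        if abs(sum(self.mixture) - 1.0) > 1e-9:
            raise SpecError(f"mixture sums to {sum(self.mixture)}, expected 1")
        if len(self.mixture) != self.n_haplotypes:
            raise SpecError("mixture length must equal n_haplotypes")
        if not (0 <= self.per_base_error < 0.5):
            raise SpecError("per_base_error must be in [0, 0.5)")
        if self.its2_length > self.read_length:
            raise SpecError("no read can span: its2_length > read_length")
        if self.its2_length + 2 * self.flank_length > self.reference_length:
            raise SpecError("window plus flanks exceeds reference length")
        if self.anchor_length > self.flank_length:
            raise SpecError("anchor_length must not exceed flank_length")
        ilo, ihi = self.insert_range
        if not (self.read_length <= ilo <= ihi):
            raise SpecError("insert_range must satisfy read_length <= lo <= hi")
        if ihi > self.reference_length:
            raise SpecError("insert_range upper bound exceeds reference length")

    @property
    def span(self) -> int:
        """Bases a read must cover to count as spanning: window + both anchors."""
        return self.its2_length + 2 * self.anchor_length


@dataclass
class ReadSimTruth:
    """Exact bookkeeping of one simulated library."""

    sample_id: str
    mixture: dict[str, float]
    spanning_counts: dict[str, int]
    n_fragments: int
    n_reads: int

    @property
    def total_spanning(self) -> int:
        return sum(self.spanning_counts.values())

    @property
    def spanning_frequencies(self) -> dict[str, float]:
        total = self.total_spanning
        return {k: v / total for k, v in self.spanning_counts.items()} if total else {}


@dataclass
class PlastomePairTruth:
    indels: dict[str, int]
    n_substitutions: int
    len_a: int
    len_b: int


@dataclass
class CohortSample:
    sample_id: str
    status: str  # parental_A | parental_B | hybrid
    plastid_type: str  # A | B
    mixture: dict[str, float]
    read_truth: Optional[ReadSimTruth] = None


@dataclass
class CohortResult:
    reference: SequenceRecord
    window: ITS2Window
    catalog: HaplotypeCatalog
    reads: dict[str, tuple[ReadBatch, ReadBatch]]
    morphology: pd.DataFrame
    truth: list[CohortSample]


def _rng(seed: int, stream: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, extra]))


# ---------------------------------------------------------------------------
# nrDNA reference and ITS2 haplotypes


def make_nrdna_reference(spec: SimulationSpec) -> tuple[SequenceRecord, ITS2Window]:
    """A random nrDNA-like reference with a centred ITS2 window.

    The window's flanking anchors are guaranteed unique on the forward
    strand (redrawn deterministically otherwise), so anchored extraction is
    unambiguous on error-free data.
    """
    rng = _rng(spec.seed, _STREAM_NRDNA)
    L = spec.reference_length
    start = (L - spec.its2_length) // 2
    for _attempt in range(100):
        seq = _dna.decode(_dna.random_bases(rng, L))
        reference = SequenceRecord(id="nrDNA_ref", residues=seq)
        try:
            window = locate_window(
                reference, start, spec.its2_length, spec.anchor_length
            )
        except Exception:
            continue
        return reference, window
    raise SpecError("could not draw a reference with unique window anchors")


def make_haplotypes(
    reference_window: str, n: int, subs: int, seed: int
) -> HaplotypeCatalog:
    """n distinct window variants, each ``subs`` substitutions from the window.

    Hap1 is the window itself; Hap2..HapN each differ from it at exactly
    ``subs`` positions. Pairwise distinctness is enforced.
    """
    if n < 1:
        raise SpecError("need at least one haplotype")
    if subs < 0:
        raise SpecError("substitutions_per_haplotype must be >= 0")
    window = _dna.normalize(reference_window, allow_gap=False)
    if subs == 0 and n > 1:
        raise SpecError("cannot build >1 distinct haplotype with 0 substitutions")
    if subs > len(window):
        raise SpecError("more substitutions than window positions")
    rng = _rng(seed, _STREAM_HAPLOTYPES)
    base = _dna.encode(window).copy()
    seqs = {window}
    out = {"Hap1": window}
    k = 2
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 1000 * n:
            raise SpecError(
                f"could not construct {n} distinct haplotypes at {subs} substitutions"
            )
        positions = rng.choice(len(window), size=subs, replace=False)
        variant = base.copy()
        idx = _dna._BASE_INDEX[variant[positions]]
        variant[positions] = _dna._INDEX_BASE[
            (idx + rng.integers(1, 4, subs)) % 4
        ]
        seq = _dna.decode(variant)
        if seq in seqs:
            continue
        seqs.add(seq)
        out[f"Hap{k}"] = seq
        k += 1
    return HaplotypeCatalog(out)


# ---------------------------------------------------------------------------
# read simulation


def _expected_spans_per_fragment(
    L: int, span_start: int, span_end: int, rl: int, ilo: int, ihi: int
) -> float:
    """Expected window-spanning reads per fragment, by exact enumeration.

    Fragments have insert length uniform on [ilo, ihi] and start uniform on
    the valid range; mate 1 is the first rl bases, mate 2 the last rl bases
    (reverse-complemented). A read spans iff its interval covers
    [span_start, span_end).
    """
    inserts = np.arange(ilo, ihi + 1)
    n_starts = L - inserts + 1
    lo1, hi1 = span_end - rl, span_start
    c1 = np.clip(np.minimum(hi1, L - inserts) - max(lo1, 0) + 1, 0, None)
    lo2 = span_end - inserts
    hi2 = span_start + rl - inserts
    c2 = np.clip(
        np.minimum(hi2, L - inserts) - np.maximum(lo2, 0) + 1, 0, None
    )
    return float(np.mean((c1 + c2) / n_starts))


def simulate_reads(
    reference: SequenceRecord,
    window: ITS2Window,
    catalog: HaplotypeCatalog,
    spec: SimulationSpec,
    sample_id: str = "sample",
) -> tuple[ReadBatch, ReadBatch, ReadSimTruth]:
    """Paired reads from a template pool mixing ITS2 haplotypes.

    Each fragment samples one haplotype from ``spec.mixture`` (one molecule,
    one repeat copy) and is placed uniformly on the template in which the
    window is replaced by that haplotype. Substitution errors are applied
    per base at ``spec.per_base_error``. The number of fragments is chosen
    so the expected count of window-spanning reads reaches
    ``spec.n_spanning_reads_target``; the truth records the realised
    per-haplotype spanning-read counts (reads covering the anchored span).
    """
    if len(spec.mixture) != len(catalog):
        raise SpecError("mixture length must equal catalog size")
    if spec.read_length < window.span:
        raise SpecError(
            f"no read can span: read_length {spec.read_length} < anchored "
            f"span {window.span}"
        )
    names = catalog.names
    ref = _dna.encode(reference.residues)
    templates = np.vstack(
        [
            np.concatenate(
                [ref[: window.start], _dna.encode(catalog[n]), ref[window.end :]]
            )
            for n in names
        ]
    )
    L = templates.shape[1]
    rl = spec.read_length
    ilo, ihi = spec.insert_range
    if ihi > L:
        raise SpecError("insert upper bound exceeds template length")
    span_start = window.start - window.anchor_len
    span_end = window.end + window.anchor_len
    e_span = _expected_spans_per_fragment(L, span_start, span_end, rl, ilo, ihi)
    if e_span <= 0:
        raise SpecError("no fragment placement yields a spanning read")
    n_fragments = math.ceil(spec.n_spanning_reads_target / e_span)

    rng = _rng(spec.seed, _STREAM_READS)
    mixture = np.asarray(spec.mixture, dtype=float)
    # (n_hap, L - rl + 1, rl) zero-copy view of every read placement
    placements = np.lib.stride_tricks.sliding_window_view(templates, rl, axis=1)
    chunks1, chunks2 = [], []
    span_counts = np.zeros(len(names), dtype=np.int64)
    done = 0
    while done < n_fragments:
        m = min(_CHUNK_FRAGMENTS, n_fragments - done)
        done += m
        inserts = rng.integers(ilo, ihi + 1, m)
        starts = (rng.random(m) * (L - inserts + 1)).astype(np.int64)
        haps = rng.choice(len(names), size=m, p=mixture)
        m2 = starts + inserts - rl
        r1 = placements[haps, starts]
        r2 = np.ascontiguousarray(_dna.revcomp_arr(placements[haps, m2]))
        _dna.apply_substitution_errors(r1, spec.per_base_error, rng)
        _dna.apply_substitution_errors(r2, spec.per_base_error, rng)
        s1 = (starts <= span_start) & (starts + rl >= span_end)
        s2 = (m2 <= span_start) & (m2 + rl >= span_end)
        span_counts += np.bincount(haps[s1], minlength=len(names))
        span_counts += np.bincount(haps[s2], minlength=len(names))
        chunks1.append(r1)
        chunks2.append(r2)
    reads1 = ReadBatch(
        seqs=np.ascontiguousarray(np.concatenate(chunks1)),
        mate=1,
        quality=spec.base_quality,
        id_prefix=f"{sample_id}:",
    )
    reads2 = ReadBatch(
        seqs=np.ascontiguousarray(np.concatenate(chunks2)),
        mate=2,
        quality=spec.base_quality,
        id_prefix=f"{sample_id}:",
    )
    truth = ReadSimTruth(
        sample_id=sample_id,
        mixture={n: float(f) for n, f in zip(names, mixture)},
        spanning_counts={n: int(c) for n, c in zip(names, span_counts)},
        n_fragments=n_fragments,
        n_reads=2 * n_fragments,
    )
    return reads1, reads2, truth


# ---------------------------------------------------------------------------
# plastome pair with planted IGS indels

_GENE_ORDER = (
    "psbA",
    "matK",
    "rpl20",
    "rps12",
    "atpA",
    "rpl33",
    "rps18",
    "rbcL",
    "ndhF",
    "rpoB",
)


def make_plastome_pair(
    spec: SimulationSpec,
) -> tuple[
    SequenceRecord, SequenceRecord, tuple[list[Feature], list[Feature]], PlastomePairTruth
]:
    """Two plastome types: B = A + substitutions + planted IGS insertions.

    Genome A carries a synthetic gene annotation (including rpl20/rps12 and
    rpl33/rps18 flanking two intergenic spacers). Genome B differs by
    Bernoulli substitutions at ``plastome_snp_rate`` and by insertions of
    the planted lengths in the named IGS regions, so len(B) - len(A) equals
    the summed indel lengths and each region's length delta equals its
    planted indel exactly.
    """
    rng = _rng(spec.seed, _STREAM_PLASTOME)
    L = spec.plastome_length
    k = len(_GENE_ORDER)
    gene_lengths = rng.integers(300, 1501, k)
    gaps = rng.integers(150, 801, k - 1)
    used = int(gene_lengths.sum() + gaps.sum())
    if used + 200 > L:
        raise SpecError(
            f"plastome_length {L} too short for the synthetic annotation "
            f"({used + 200} bp needed)"
        )
    # first gene starts at 0; the remainder of the circle is the wrap IGS
    features_a: list[Feature] = []
    pos = 0
    for i, name in enumerate(_GENE_ORDER):
        end = pos + int(gene_lengths[i])
        features_a.append(
            Feature(
                seqid="plastomeA",
                start=pos,
                end=end,
                strand="+" if i % 2 == 0 else "-",
                type="gene",
                name=name,
            )
        )
        pos = end
        if i < k - 1:
            pos += int(gaps[i])
    seq_a = _dna.random_bases(rng, L)
    igs_by_name = {}
    for left, right in zip(features_a, features_a[1:]):
        igs_by_name[f"{left.name}-{right.name}"] = (left.end, right.start)
    igs_by_name[f"{features_a[-1].name}-{features_a[0].name}"] = (
        features_a[-1].end,
        L,
    )

    seq_b, n_subs = _dna.substitute_sites(seq_a, spec.plastome_snp_rate, rng)
    indels: dict[str, int] = {}
    for region, length in spec.planted_indels:
        if region not in igs_by_name:
            raise SpecError(
                f"planted indel region {region!r} not in the generated "
                f"annotation; available: {sorted(igs_by_name)}"
            )
        start, end = igs_by_name[region]
        if length >= end - start:
            raise SpecError(
                f"indel of {length} bp does not fit in IGS {region!r} "
                f"({end - start} bp)"
            )
        indels[region] = int(length)
    # insert right-to-left so earlier coordinates stay valid
    features_b = [replace(f, seqid="plastomeB") for f in features_a]
    for region in sorted(indels, key=lambda r: igs_by_name[r][0], reverse=True):
        start, end = igs_by_name[region]
        at = (start + end) // 2
        insert = _dna.random_bases(rng, indels[region])
        seq_b = np.concatenate([seq_b[:at], insert, seq_b[at:]])
        shifted = []
        for f in features_b:
            if f.start >= at:
                shifted.append(
                    replace(f, start=f.start + indels[region], end=f.end + indels[region])
                )
            else:
                shifted.append(f)
        features_b = shifted

    rec_a = SequenceRecord(id="plastomeA", residues=_dna.decode(seq_a))
    rec_b = SequenceRecord(id="plastomeB", residues=_dna.decode(seq_b))
    truth = PlastomePairTruth(
        indels=indels,
        n_substitutions=n_subs,
        len_a=len(rec_a),
        len_b=len(rec_b),
    )
    return rec_a, rec_b, (features_a, features_b), truth


# ---------------------------------------------------------------------------
# cohorts

COHORT_HAPLOTYPE_NAMES = ("Type1", "US1", "Type2a", "Type2d", "US2", "US3", "US4")

# Status-typical ITS2 compositions. Parental A (the short, aquatic taxon)
# keeps just two haplotypes; parental B (the tall, terrestrial taxon) and
# the hybrids carry northern-type multi-haplotype repeats including Type1
# and US1. A southern-type composition (lacking Type1/US1) is provided for
# reference-profile use. Minor shares sit at 4-26%, the range such pies
# typically show.
STATUS_MIXTURES: dict[str, dict[str, float]] = {
    "parental_A": {"Type1": 0.55, "US1": 0.45},
    "parental_B": {
        "Type1": 0.26,
        "US1": 0.14,
        "Type2a": 0.22,
        "Type2d": 0.14,
        "US2": 0.12,
        "US3": 0.08,
        "US4": 0.04,
    },
    "hybrid": {
        "Type1": 0.24,
        "US1": 0.12,
        "Type2a": 0.26,
        "Type2d": 0.14,
        "US2": 0.12,
        "US3": 0.08,
        "US4": 0.04,
    },
}

SOUTHERN_MIXTURE: dict[str, float] = {
    "Type2a": 0.34,
    "Type2d": 0.22,
    "US2": 0.18,
    "US3": 0.14,
    "US4": 0.12,
}

_MORPHOLOGY_BY_STATUS = {
    # hybrids resemble parental B above ground but carry the A plastome
    "parental_A": dict(
        inflorescence="short_ovoid",
        flared_ocreae=True,
        leaf_shape="lanceolate",
        height="under_30cm",
    ),
    "parental_B": dict(
        inflorescence="long_cylindrical",
        flared_ocreae=False,
        leaf_shape="lanceolate",
        height="over_30cm",
    ),
    "hybrid": dict(
        inflorescence="long_cylindrical",
        flared_ocreae=False,
        leaf_shape="lanceolate",
        height="over_30cm",
    ),
}

_DEFAULT_PLASTID = {"parental_A": "A", "parental_B": "B", "hybrid": "A"}


def simulate_cohort(
    sheet: Sequence[tuple],
    spec: SimulationSpec,
) -> CohortResult:
    """Per-sample reads, a morphology sheet and a truth table for a cohort.

    *sheet* rows are ``(sample_id, status)`` optionally extended with a
    plastid type and a mixture mapping; omitted fields take the
    status-typical defaults above. Statuses: parental_A, parental_B,
    hybrid. Hybrids get parental-B-like morphology with the parental-A
    plastome (the maternal-capture signature this pipeline detects).
    """
    ids = [row[0] for row in sheet]
    if len(ids) != len(set(ids)):
        raise SpecError("duplicate sample id in cohort sheet")
    reference, window = make_nrdna_reference(spec)
    base_catalog = make_haplotypes(
        reference.residues[window.start : window.end],
        n=len(COHORT_HAPLOTYPE_NAMES),
        subs=max(spec.substitutions_per_haplotype, 1),
        seed=spec.seed,
    )
    catalog = base_catalog.rename(COHORT_HAPLOTYPE_NAMES)
    reads: dict[str, tuple[ReadBatch, ReadBatch]] = {}
    morph_rows = []
    truth: list[CohortSample] = []
    for index, row in enumerate(sheet):
        sample_id, status = row[0], row[1]
        if status not in STATUS_MIXTURES:
            raise SpecError(
                f"unknown status {status!r}; expected one of "
                f"{sorted(STATUS_MIXTURES)}"
            )
        plastid = row[2] if len(row) > 2 and row[2] else _DEFAULT_PLASTID[status]
        if plastid not in ("A", "B"):
            raise SpecError(f"plastid type must be A or B, got {plastid!r}")
        mixture = dict(row[3]) if len(row) > 3 and row[3] else STATUS_MIXTURES[status]
        if abs(sum(mixture.values()) - 1.0) > 1e-9:
            raise SpecError(f"sample {sample_id!r}: mixture does not sum to 1")
        unknown = set(mixture) - set(catalog.names)
        if unknown:
            raise SpecError(f"sample {sample_id!r}: unknown haplotypes {unknown}")
        full = tuple(mixture.get(n, 0.0) for n in catalog.names)
        sample_spec = replace(
            spec,
            seed=int(
                np.random.SeedSequence([spec.seed, _STREAM_COHORT, index]).generate_state(
                    1
                )[0]
                % (2**31)
            ),
            mixture=full,
            n_haplotypes=len(catalog),
        )
        r1, r2, read_truth = simulate_reads(
            reference, window, catalog, sample_spec, sample_id=sample_id
        )
        reads[sample_id] = (r1, r2)
        morph_rows.append({"sample": sample_id, **_MORPHOLOGY_BY_STATUS[status]})
        truth.append(
            CohortSample(
                sample_id=sample_id,
                status=status,
                plastid_type=plastid,
                mixture={n: f for n, f in zip(catalog.names, full) if f > 0},
                read_truth=read_truth,
            )
        )
    morphology = pd.DataFrame(
        morph_rows,
        columns=["sample", "inflorescence", "flared_ocreae", "leaf_shape", "height"],
    )
    return CohortResult(
        reference=reference,
        window=window,
        catalog=catalog,
        reads=reads,
        morphology=morphology,
        truth=truth,
    )
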