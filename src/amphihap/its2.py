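"""Intragenomic ITS2 haplotype tallying from shotgun short reads.

The nuclear ribosomal DNA cistron is tandemly repeated; in hybrids and
polyploids, concerted evolution is incomplete and one individual can carry
several ITS2 sequence variants at skewed frequencies. With deep shotgun
data the composition can be read out directly: every read that fully spans
a fixed ITS2 window (133 bp by default) contributes one observation of one
repeat copy, and exact-sequence counting over those windows estimates the
within-individual haplotype mixture.

"Fully spans" is operationalised as anchored-pattern containment: the read
(or its reverse complement) must contain the ``anchor_len`` bases flanking
the window on each side (with at most ``max_anchor_mismatch`` mismatches
per anchor) separated by exactly the window length. Anchors make the
criterion strand-safe and keep the extracted segment in reference frame.
Counting is exact-sequence — no quality weighting, no denoising model;
sequencing noise is handled by a count/frequency floor that pools rare
variants into an "other" bin.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from . import _dna
from .errors import AmbiguityError, FormatError, SpecError
from .io import ReadBatch, ReadRecord, SequenceRecord, parse_fasta

OTHER = "other"
NO_COVERAGE = "no coverage"

__all__ = [
    "ITS2Window",
    "HaplotypeCatalog",
    "TallyResult",
    "HaplotypeProfile",
    "locate_window",
    "extract_spanning",
    "tally",
    "assign_names",
    "composition_report",
    "OTHER",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ITS2Window:
    """The tallied window on the nrDNA reference plus its flanking anchors."""

    reference_id: str
    start: int
    end: int
    left_anchor: str
    right_anchor: str

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise SpecError("window must span at least one base")
        for anchor in (self.left_anchor, self.right_anchor):
            if "N" in anchor or "-" in anchor:
                raise SpecError(f"anchor {anchor!r} contains N or gap")
            if not anchor:
                raise SpecError("empty anchor")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def anchor_len(self) -> int:
        return len(self.left_anchor)

    @property
    def span(self) -> int:
        """Total bases a read must contain: both anchors plus the window."""
        return self.length + len(self.left_anchor) + len(self.right_anchor)


class HaplotypeCatalog:
    """Named reference ITS2 haplotypes, all the same length as the window."""

    def __init__(self, entries: Mapping[str, str]):
        seqs: dict[str, str] = {}
        for name, seq in entries.items():
            seqs[name] = _dna.normalize(seq, allow_gap=False)
        if len(seqs) != len(entries):
            raise SpecError("duplicate haplotype names in catalog")
        if len(set(seqs.values())) != len(seqs):
            raise SpecError("duplicate haplotype sequences in catalog")
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise SpecError(f"catalog sequences have mixed lengths: {sorted(lengths)}")
        self._seqs = seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def __iter__(self):
        return iter(self._seqs)

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    @property
    def window_length(self) -> int:
        return len(next(iter(self._seqs.values())))

    def items(self):
        return self._seqs.items()

    def rename(self, names: Iterable[str]) -> "HaplotypeCatalog":
        names = list(names)
        if len(names) != len(self._seqs):
            raise SpecError("rename list length does not match catalog size")
        return HaplotypeCatalog(dict(zip(names, self._seqs.values())))

    @classmethod
    def from_fasta(cls, path) -> "HaplotypeCatalog":
        return cls({rec.id: rec.residues for rec in parse_fasta(path)})


@dataclass
class TallyResult:
    """Exact-sequence counts over all window-spanning segments of one library.

    ``counts`` maps surviving variant sequences (plus :data:`OTHER`) to
    counts after the noise floor; ``total_spanning`` is the number of
    spanning segments before pooling.
    """

    counts: dict[str, int]
    total_spanning: int
    n_reads: int
    n_skipped: int
    min_count: int
    min_freq: float

    @property
    def no_coverage(self) -> bool:
        return self.total_spanning == 0


@dataclass
class HaplotypeProfile:
    """Per-sample composition: catalog names, NovelK ids and "other"."""

    sample_id: str
    counts: dict[str, int]
    total_spanning: int
    catalog_names: tuple[str, ...] = ()
    variant_sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise SpecError("negative haplotype count")
        if sum(self.counts.values()) != self.total_spanning:
            raise SpecError("profile counts do not sum to total_spanning")

    @property
    def no_coverage(self) -> bool:
        return self.total_spanning == 0

    @property
    def frequencies(self) -> dict[str, float]:
        """Counts over all spanning reads (including "other")."""
        if self.total_spanning == 0:
            return {}
        return {k: v / self.total_spanning for k, v in self.counts.items()}

    def present_haplotypes(self, include_novel: bool = True) -> list[str]:
        """Named variants with non-zero counts, excluding the "other" pool."""
        out = []
        for name, count in self.counts.items():
            if name == OTHER or count == 0:
                continue
            if not include_novel and name not in self.catalog_names:
                continue
            out.append(name)
        return out

    def renormalized_frequencies(self, include_novel: bool = False) -> dict[str, float]:
        """Composition over named haplotypes only — the pie-chart convention.

        Reads whose window carries a sequencing error fall into "other";
        because errors hit all haplotypes at the same per-base rate, the
        renormalised shares remain unbiased estimates of the repeat mixture.
        """
        names = self.present_haplotypes(include_novel=include_novel)
        total = sum(self.counts[n] for n in names)
        if total == 0:
            return {}
        return {n: self.counts[n] / total for n in names}


# ---------------------------------------------------------------------------
# operations


def _find_once(haystack: str, needle: str) -> int:
    first = haystack.find(needle)
    if first == -1:
        raise SpecError(f"anchor {needle!r} not found in reference")
    if haystack.find(needle, first + 1) != -1:
        raise AmbiguityError(f"anchor {needle!r} occurs more than once in reference")
    return first


def locate_window(
    reference: SequenceRecord, start: int, length: int, anchor_len: int = 8
) -> ITS2Window:
    """Fix the tallied window on an assembled nrDNA reference.

    The two ``anchor_len``-base anchors are copied from the reference
    immediately outside the window and must each occur exactly once on the
    forward strand, otherwise extraction would be ambiguous.
    """
    seq = reference.residues
    if start - anchor_len < 0 or start + length + anchor_len > len(seq):
        raise SpecError(
            f"window [{start}, {start + length}) with {anchor_len} bp anchors "
            f"does not fit in reference of length {len(seq)}"
        )
    left = seq[start - anchor_len : start]
    right = seq[start + length : start + length + anchor_len]
    window = ITS2Window(
        reference_id=reference.id,
        start=start,
        end=start + length,
        left_anchor=left,
        right_anchor=right,
    )
    _find_once(seq, left)
    _find_once(seq, right)
    return window


def _anchor_hits(seq: str, anchor: str, max_mismatch: int) -> list[int]:
    a = _dna.encode(anchor)
    s = _dna.encode(seq)
    if s.size < a.size:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(s, a.size)
    mism = (windows != a).sum(axis=1)
    return list(np.flatnonzero(mism <= max_mismatch))


def extract_spanning(
    read: ReadRecord | str,
    window: ITS2Window,
    max_anchor_mismatch: int = 1,
    keep_length_variants: bool = False,
) -> Optional[str]:
    """The window segment of a read that fully spans the anchored window.

    Both the read and its reverse complement are searched; a hit on the
    reverse strand is returned canonicalised to reference orientation.
    Returns None for non-spanning reads, for segments containing N, and —
    unless ``keep_length_variants`` — for anchor pairs whose gap differs
    from the window length (indel-bearing copies).
    """
    seq = read.sequence if isinstance(read, ReadRecord) else read
    a = window.anchor_len
    wl = window.length
    for oriented in (seq, _dna.revcomp(seq)):
        lefts = _anchor_hits(oriented, window.left_anchor, max_anchor_mismatch)
        if not lefts:
            continue
        rights = set(_anchor_hits(oriented, window.right_anchor, max_anchor_mismatch))
        for i in lefts:
            if keep_length_variants:
                candidates = sorted(j for j in rights if j > i + a)
            else:
                candidates = [i + a + wl] if i + a + wl in rights else []
            for j in candidates:
                segment = oriented[i + a : j]
                if "N" in segment:
                    return None
                return segment
    return None


def _batch_segments(
    seqs: np.ndarray, window: ITS2Window, max_anchor_mismatch: int
) -> tuple[Counter, int]:
    """Counter of spanning window segments (as bytes) in an (n, L) batch.

    Matches the scalar :func:`extract_spanning` with the default
    exact-length gap: strand-major, offset-minor first hit per read.
    Returns (segment counter, n reads skipped for N in segment).
    """
    n, L = seqs.shape
    a = window.anchor_len
    wl = window.length
    span = window.span
    counter: Counter = Counter()
    n_skipped = 0
    if L < span or n == 0:
        return counter, n_skipped
    left = _dna.encode(window.left_anchor)
    right = _dna.encode(window.right_anchor)
    claimed = np.zeros(n, dtype=bool)
    for arr in (seqs, _dna.revcomp_arr(seqs)):
        for off in range(L - span + 1):
            lm = (arr[:, off : off + a] != left).sum(axis=1) <= max_anchor_mismatch
            if not lm.any():
                continue
            rm = (
                arr[:, off + a + wl : off + span] != right
            ).sum(axis=1) <= max_anchor_mismatch
            hit = lm & rm & ~claimed
            if not hit.any():
                continue
            claimed |= hit
            segs = np.ascontiguousarray(arr[hit, off + a : off + a + wl])
            has_n = (segs == _dna.N).any(axis=1)
            n_skipped += int(has_n.sum())
            for row in segs[~has_n]:
                counter[row.tobytes()] += 1
    return counter, n_skipped


def _iter_batches(reads) -> Iterable[np.ndarray]:
    if isinstance(reads, ReadBatch):
        yield reads.seqs
        return
    if isinstance(reads, (tuple, list)) and all(
        isinstance(r, ReadBatch) for r in reads
    ):
        for batch in reads:
            yield batch.seqs
        return
    by_length: dict[int, list[np.ndarray]] = {}
    pending = 0
    for read in reads:
        seq = read.sequence if isinstance(read, ReadRecord) else str(read)
        arr = _dna.encode(seq)
        by_length.setdefault(arr.size, []).append(arr)
        pending += 1
        if pending >= 100_000:  # bound memory on streamed FASTQ
            for group in by_length.values():
                yield np.vstack(group)
            by_length.clear()
            pending = 0
    for group in by_length.values():
        yield np.vstack(group)


def tally(
    reads,
    window: ITS2Window,
    min_count: int = 2,
    min_freq: float = 0.005,
    max_anchor_mismatch: int = 1,
    keep_length_variants: bool = False,
    max_spanning: Optional[int] = None,
    subsample_seed: int = 0,
) -> TallyResult:
    """Exact-sequence counts of window-spanning segments in a read set.

    *reads* may be a :class:`ReadBatch`, a pair/list of batches, or any
    iterable of :class:`ReadRecord` / plain sequences (streamed). Variants
    with count below ``max(min_count, min_freq * total_spanning)`` are
    pooled into :data:`OTHER`. Zero spanning reads is not an error: the
    result is flagged ``no_coverage``.

    ``max_spanning`` caps the tally at a fixed number of spanning reads by
    seeded subsampling without replacement (equivalent to reservoir
    sampling over the read stream) — for strict emulation of a
    fixed-depth protocol. By default all spanning reads are used.
    """
    counter: Counter = Counter()
    n_reads = 0
    n_skipped = 0
    if keep_length_variants:
        # Variable-gap search has no fixed segment width; scalar path.
        read_iter = (
            reads.to_records()
            if isinstance(reads, ReadBatch)
            else (r for batch in reads for r in batch.to_records())
            if isinstance(reads, (tuple, list))
            and all(isinstance(r, ReadBatch) for r in reads)
            else reads
        )
        for read in read_iter:
            n_reads += 1
            segment = extract_spanning(
                read, window, max_anchor_mismatch, keep_length_variants=True
            )
            if segment is None:
                n_skipped += 1
            else:
                counter[segment] += 1
        counts_str = dict(counter)
    else:
        for seqs in _iter_batches(reads):
            n_reads += seqs.shape[0]
            batch_counts, batch_n_skip = _batch_segments(
                seqs, window, max_anchor_mismatch
            )
            counter.update(batch_counts)
            n_skipped += batch_n_skip
        counts_str = {k.decode("ascii"): v for k, v in counter.items()}
    if max_spanning is not None and sum(counts_str.values()) > max_spanning:
        rng = np.random.default_rng(subsample_seed)
        variants = sorted(counts_str)  # stable order for determinism
        drawn = rng.multivariate_hypergeometric(
            [counts_str[v] for v in variants], max_spanning
        )
        counts_str = {v: int(c) for v, c in zip(variants, drawn) if c > 0}
    total = sum(counts_str.values())
    threshold = max(min_count, min_freq * total)
    kept: dict[str, int] = {}
    pooled = 0
    for seq, count in counts_str.items():
        if count < threshold:
            pooled += count
        else:
            kept[seq] = count
    if pooled:
        kept[OTHER] = pooled
    return TallyResult(
        counts=kept,
        total_spanning=total,
        n_reads=n_reads,
        n_skipped=n_reads - total,
        min_count=min_count,
        min_freq=min_freq,
    )


def assign_names(
    result: TallyResult,
    catalog: HaplotypeCatalog,
    max_mismatch: int = 0,
    sample_id: str = "sample",
) -> HaplotypeProfile:
    """Match surviving variants against the catalog and name the rest NovelK.

    Matching is exact by default; with ``max_mismatch`` > 0 a variant within
    that Hamming distance of two catalog entries raises
    :class:`AmbiguityError`. Unmatched variants are named Novel1..NovelK in
    descending count order (lexicographic tie-break on sequence).
    """
    by_seq = {seq: name for name, seq in catalog.items()}
    named: dict[str, int] = {}
    sequences: dict[str, str] = {}
    unmatched: list[tuple[str, int]] = []
    length_variants: list[tuple[str, int]] = []
    for seq, count in result.counts.items():
        if seq == OTHER:
            continue
        if len(catalog) and len(seq) != catalog.window_length:
            # indel-bearing copies surface only under keep_length_variants
            length_variants.append((seq, count))
            continue
        if max_mismatch == 0:
            match = by_seq.get(seq)
        else:
            hits = [
                name
                for name, cseq in catalog.items()
                if len(cseq) == len(seq) and _dna.hamming(seq, cseq) <= max_mismatch
            ]
            if len(hits) > 1:
                raise AmbiguityError(
                    f"variant matches {len(hits)} catalog entries within "
                    f"{max_mismatch} mismatches: {', '.join(sorted(hits))}"
                )
            match = hits[0] if hits else None
        if match is None:
            unmatched.append((seq, count))
        else:
            named[match] = named.get(match, 0) + count
            sequences[match] = catalog[match]
    unmatched.sort(key=lambda item: (-item[1], item[0]))
    for k, (seq, count) in enumerate(unmatched, start=1):
        name = f"Novel{k}"
        named[name] = count
        sequences[name] = seq
    length_variants.sort(key=lambda item: (-item[1], item[0]))
    for k, (seq, count) in enumerate(length_variants, start=1):
        name = f"len{len(seq)}.{k}"
        named[name] = count
        sequences[name] = seq
    if OTHER in result.counts:
        named[OTHER] = result.counts[OTHER]
    return HaplotypeProfile(
        sample_id=sample_id,
        counts=named,
        total_spanning=result.total_spanning,
        catalog_names=tuple(catalog.names),
        variant_sequences=sequences,
    )


def composition_report(
    profiles: list[HaplotypeProfile],
    out_dir,
    write_pies: bool = True,
) -> pd.DataFrame:
    """Long-format TSV plus one pie chart per sample.

    The TSV carries raw counts and frequencies; the human-readable percent
    column is rounded to whole percent, matching how such compositions are
    conventionally reported. Returns the report as a DataFrame.
    """
    if not profiles:
        raise SpecError("composition_report needs at least one profile")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for profile in profiles:
        if profile.no_coverage:
            rows.append(
                {
                    "sample": profile.sample_id,
                    "haplotype": NO_COVERAGE,
                    "count": 0,
                    "frequency": float("nan"),
                    "percent": float("nan"),
                }
            )
            continue
        for name, count in sorted(
            profile.counts.items(), key=lambda kv: (kv[0] == OTHER, -kv[1], kv[0])
        ):
            freq = count / profile.total_spanning
            rows.append(
                {
                    "sample": profile.sample_id,
                    "haplotype": name,
                    "count": count,
                    "frequency": freq,
                    "percent": round(100 * freq),
                }
            )
    df = pd.DataFrame(rows)
    tsv = out_dir / "its2_composition.tsv"
    with open(tsv, "w") as out:
        first = profiles[0]
        out.write("# amphihap ITS2 composition report\n")
        out.write(f"# samples: {len(profiles)}\n")
        out.write("# noise floor: see per-run tally parameters\n")
        df.to_csv(out, sep="\t", index=False)
    if write_pies:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for profile in profiles:
            fig, ax = plt.subplots(figsize=(4, 4))
            if profile.no_coverage:
                ax.text(0.5, 0.5, NO_COVERAGE, ha="center", va="center")
                ax.set_axis_off()
            else:
                items = sorted(
                    profile.counts.items(),
                    key=lambda kv: (kv[0] == OTHER, -kv[1], kv[0]),
                )
                ax.pie(
                    [c for _, c in items],
                    labels=[n for n, _ in items],
                    autopct="%1.0f%%",
                )
            ax.set_title(profile.sample_id)
            fig.savefig(out_dir / f"pie_{profile.sample_id}.png", dpi=100)
            plt.close(fig)
    return df
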