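"""Intergenic-spacer indel markers and in-silico PCR genotyping.

Plastomes of closely related taxa differ mostly by substitutions plus
occasional indels concentrated in intergenic spacers (IGS). A pair of
primers flanking such an indel amplifies different-sized fragments from
the two plastome types, giving a cheap gel-resolvable assay for the
(maternally inherited) plastid type of many individuals. This module does
the computational half: derive IGS regions from annotations, rank
homologous regions by length difference between two genomes, predict PCR
products, and call genotypes (A / B / both / none) from observed fragment
lengths.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from . import _dna
from .errors import PairingError, SpecError
from .io import Feature, SequenceRecord

log = logging.getLogger("amphihap.markers")

__all__ = [
    "IgsInterval",
    "IgsRegion",
    "PrimerPair",
    "AmpliconResult",
    "GenotypeCall",
    "derive_igs",
    "rank_markers",
    "design_primer_pair",
    "in_silico_pcr",
    "genotype",
]


@dataclass(frozen=True)
class IgsInterval:
    """One genome's half of an IGS region, 0-based half-open.

    For the wrap-around spacer of a circular genome, ``end`` may exceed the
    genome length; ``length`` stays correct (end - start).
    """

    name: str  # "geneL-geneR"
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IgsRegion:
    """A name-paired IGS region across two genomes, ranked by size delta."""

    name: str
    interval_a: IgsInterval
    interval_b: IgsInterval

    @property
    def len_a(self) -> int:
        return self.interval_a.length

    @property
    def len_b(self) -> int:
        return self.interval_b.length

    @property
    def delta(self) -> int:
        return abs(self.len_a - self.len_b)


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, each written 5'->3' on its own strand."""

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for primer in (self.forward, self.reverse):
            if len(primer) < 15:
                raise SpecError(f"primer {primer!r} shorter than 15 bases")
            if "N" in primer or "-" in primer:
                raise SpecError(f"primer {primer!r} contains N or gap")


@dataclass(frozen=True)
class AmpliconResult:
    template_id: str
    start: int
    end: int
    mismatches_fwd: int
    mismatches_rev: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    marker: str
    call: str  # A | B | both | none
    observed_lengths: tuple[int, ...]
    resolvable: bool = True


# ---------------------------------------------------------------------------
# IGS derivation and ranking


def derive_igs(features: Sequence[Feature], genome_length: int) -> list[IgsInterval]:
    """Spacers between consecutive gene features of a circular genome.

    Regions are named "geneL-geneR"; zero-length gaps are omitted and gaps
    under overlapping genes are skipped with a warning. The circle is
    closed by a final lastGene-firstGene interval whose ``end`` runs past
    ``genome_length``.
    """
    genes = sorted(
        (f for f in features if f.type == "gene"), key=lambda f: (f.start, f.end)
    )
    if len(genes) < 2:
        raise SpecError("need at least 2 gene features to derive IGS regions")
    out: list[IgsInterval] = []
    for left, right in zip(genes, genes[1:]):
        if right.start < left.end:
            log.warning(
                "genes %s and %s overlap; skipping their spacer", left.name, right.name
            )
            continue
        if right.start == left.end:
            continue
        out.append(
            IgsInterval(
                name=f"{left.name}-{right.name}", start=left.end, end=right.start
            )
        )
    wrap_length = genome_length - genes[-1].end + genes[0].start
    if wrap_length > 0:
        out.append(
            IgsInterval(
                name=f"{genes[-1].name}-{genes[0].name}",
                start=genes[-1].end,
                end=genome_length + genes[0].start,
            )
        )
    return out


def rank_markers(
    igs_a: Iterable[IgsInterval],
    igs_b: Iterable[IgsInterval],
    top_k: Optional[int] = None,
) -> list[IgsRegion]:
    """Pair IGS regions by name and sort by |lenA - lenB| descending.

    Ties break lexicographically by region name, which also makes the
    result invariant to input order. Regions present in only one genome
    are dropped; no shared names at all is a pairing error. When every
    delta is zero the ranking is still returned but a warning notes that
    no discriminating marker exists.
    """
    a_by_name = {r.name: r for r in igs_a}
    b_by_name = {r.name: r for r in igs_b}
    shared = sorted(set(a_by_name) & set(b_by_name))
    if not shared:
        raise PairingError("no IGS region names shared between the two genomes")
    regions = [
        IgsRegion(name=n, interval_a=a_by_name[n], interval_b=b_by_name[n])
        for n in shared
    ]
    regions.sort(key=lambda r: (-r.delta, r.name))
    if regions[0].delta == 0:
        log.warning("all paired IGS regions have equal lengths: no discriminating marker")
    return regions[:top_k] if top_k is not None else regions


# ---------------------------------------------------------------------------
# primers and in-silico PCR


def design_primer_pair(
    template_a: SequenceRecord,
    template_b: SequenceRecord,
    region_a: IgsInterval,
    region_b: IgsInterval,
    primer_length: int = 20,
    max_offset: int = 400,
) -> PrimerPair:
    """Primers flanking a paired IGS region, identical in both genomes.

    Scans outward from the region boundaries (into the conserved flanking
    genes) for the nearest ``primer_length`` windows at the same distance
    from the boundary in both genomes with identical sequence — the
    in-silico analogue of designing an assay that works on both plastome
    types. The reverse primer is returned 5'->3' on the minus strand.
    """
    seq_a, seq_b = template_a.residues, template_b.residues
    fwd = rev = None
    for d in range(0, max_offset):
        sa = region_a.start - d - primer_length
        sb = region_b.start - d - primer_length
        if sa < 0 or sb < 0:
            break
        cand_a = seq_a[sa : sa + primer_length]
        if cand_a == seq_b[sb : sb + primer_length] and "N" not in cand_a:
            fwd = cand_a
            break
    for d in range(0, max_offset):
        sa = region_a.end + d
        sb = region_b.end + d
        if sa + primer_length > len(seq_a) or sb + primer_length > len(seq_b):
            break
        cand_a = seq_a[sa : sa + primer_length]
        if cand_a == seq_b[sb : sb + primer_length] and "N" not in cand_a:
            rev = _dna.revcomp(cand_a)
            break
    if fwd is None or rev is None:
        raise SpecError(
            f"no conserved primer sites found around region {region_a.name!r}"
        )
    return PrimerPair(name=region_a.name, forward=fwd, reverse=rev)


def _binding_sites(
    template: np.ndarray,
    primer: str,
    max_mismatch: int,
    three_prime_exact: int,
    three_prime_left: bool,
) -> list[tuple[int, int]]:
    """Plus-strand positions where *primer*'s plus-strand image binds.

    ``three_prime_left`` selects which end of the image carries the primer's
    3' terminus (left end for minus-strand annealing). The 3'-terminal
    ``three_prime_exact`` bases must match exactly; elsewhere up to
    ``max_mismatch`` mismatches are allowed. Returns (start, mismatches).
    """
    p = _dna.encode(primer)
    if template.size < p.size:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(template, p.size)
    diff = windows != p
    if three_prime_left:
        core = diff[:, :three_prime_exact]
        rest = diff[:, three_prime_exact:]
    else:
        core = diff[:, p.size - three_prime_exact :]
        rest = diff[:, : p.size - three_prime_exact]
    mism = rest.sum(axis=1)
    ok = (~core.any(axis=1)) & (mism <= max_mismatch)
    return [(int(i), int(mism[i])) for i in np.flatnonzero(ok)]


def in_silico_pcr(
    template: SequenceRecord,
    primers: PrimerPair,
    max_mismatch: int = 2,
    max_product: int = 5000,
    three_prime_exact: int = 5,
) -> list[AmpliconResult]:
    """Predicted PCR products of a primer pair on a linear template.

    A product forms between a primer annealing to the minus strand (its
    sequence appears on the plus strand; extension rightward) and one
    annealing to the plus strand (its reverse complement appears on the
    plus strand; extension leftward), in either primer assignment. All
    convergent pairings with length <= ``max_product`` are reported,
    sorted by length. No product is not an error: the list is empty.
    """
    t = _dna.encode(template.residues)
    results = []
    pairings = (
        (primers.forward, primers.reverse),
        (primers.reverse, primers.forward),
    )
    for right_extender, left_extender in pairings:
        starts = _binding_sites(
            t, right_extender, max_mismatch, three_prime_exact, three_prime_left=False
        )
        ends = _binding_sites(
            t,
            _dna.revcomp(left_extender),
            max_mismatch,
            three_prime_exact,
            three_prime_left=True,
        )
        for s, mm_f in starts:
            for e, mm_r in ends:
                end = e + len(left_extender)
                if end <= s:
                    continue
                if end - s > max_product:
                    continue
                results.append(
                    AmpliconResult(
                        template_id=template.id,
                        start=s,
                        end=end,
                        mismatches_fwd=mm_f,
                        mismatches_rev=mm_r,
                    )
                )
    # the two pairings can rediscover the same interval; keep one
    unique = {(r.start, r.end): r for r in sorted(results, key=lambda r: (r.start, r.end))}
    return sorted(unique.values(), key=lambda r: (r.length, r.start))


# ---------------------------------------------------------------------------
# genotyping


def genotype(
    observed: Sequence[int],
    expected: tuple[int, int],
    resolution: int = 10,
    tolerance: int = 5,
    sample_id: str = "sample",
    marker: str = "marker",
) -> GenotypeCall:
    """Call the plastid type from observed amplicon lengths.

    If the expected sizes differ by less than ``resolution`` (agarose
    resolvability, default 10 bp) the marker cannot discriminate and the
    call is "none" with ``resolvable=False``. Otherwise each observed
    length is matched to the nearest expected size within ``tolerance``;
    matching both gives "both" (two plastome types co-occurring, as in a
    mixed population sample).
    """
    len_a, len_b = expected
    obs = tuple(int(x) for x in observed)
    if abs(len_a - len_b) < resolution:
        log.warning(
            "marker %s: expected sizes %d/%d closer than %d bp resolution",
            marker,
            len_a,
            len_b,
            resolution,
        )
        return GenotypeCall(
            sample_id=sample_id, marker=marker, call="none",
            observed_lengths=obs, resolvable=False,
        )
    hit_a = any(abs(x - len_a) <= tolerance for x in obs)
    hit_b = any(abs(x - len_b) <= tolerance for x in obs)
    if hit_a and hit_b:
        call = "both"
    elif hit_a:
        call = "A"
    elif hit_b:
        call = "B"
    else:
        call = "none"
    return GenotypeCall(
        sample_id=sample_id, marker=marker, call=call, observed_lengths=obs
    )
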