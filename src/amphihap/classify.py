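"""Hybrid detection from morphology, plastid type and ITS2 composition.

Hybridisation leaves a characteristic cyto-nuclear signature: the plastome
is inherited from the seed parent only, while morphology and the nuclear
ribosomal repeats reflect both parents. An individual whose three evidence
channels (morphology key, plastid genotype, ITS2 composition class) agree
is a parental; any disagreement among determinate channels marks a hybrid,
and the plastid channel then names the maternal parent.

The default taxon labels follow the motivating system: taxon A
("stipulacea", the short aquatic form, plastome type A) and taxon B
("coccinea", the tall terrestrial form, plastome type B), with ITS2
classes "stipulacea", "coccinea_northern" and "coccinea_southern".
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis

from .errors import InputError, SpecError
from .its2 import OTHER, HaplotypeProfile

AMBIGUOUS = "ambiguous"

__all__ = [
    "MorphologyRecord",
    "ReferenceProfile",
    "ReferenceProfileSet",
    "EvidenceBundle",
    "HybridVerdict",
    "call_morphology",
    "call_its2_class",
    "classify_sample",
    "cohort_report",
    "AMBIGUOUS",
]


_INFLORESCENCE = {"short_ovoid", "long_cylindrical"}
_LEAF = {"oblong", "lanceolate"}
_HEIGHT = {"under_30cm", "over_30cm"}


@dataclass(frozen=True)
class MorphologyRecord:
    """The four-field key used in the field: inflorescence shape, flared
    ocreae (sheathing stipules of stranded aquatic forms), leaf shape and
    plant height."""

    sample_id: str
    inflorescence: str
    flared_ocreae: bool
    leaf_shape: str
    height: str

    def __post_init__(self) -> None:
        if self.inflorescence not in _INFLORESCENCE:
            raise InputError(f"unknown inflorescence {self.inflorescence!r}")
        if self.leaf_shape not in _LEAF:
            raise InputError(f"unknown leaf shape {self.leaf_shape!r}")
        if self.height not in _HEIGHT:
            raise InputError(f"unknown height {self.height!r}")
        if not isinstance(self.flared_ocreae, (bool, np.bool_)):
            raise InputError("flared_ocreae must be boolean")


@dataclass(frozen=True)
class ReferenceProfile:
    """Mean composition of one ITS2 class plus its diagnostic rules."""

    frequencies: Mapping[str, float]
    diagnostic_present: frozenset = frozenset()
    diagnostic_absent: frozenset = frozenset()

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"reference profile sums to {total}, expected 1")


class ReferenceProfileSet(dict):
    """class name -> ReferenceProfile; plain dict with validation."""

    def __init__(self, entries: Mapping[str, ReferenceProfile]):
        super().__init__(entries)
        if len(set(entries)) != len(entries):
            raise SpecError("duplicate class names")


@dataclass(frozen=True)
class EvidenceBundle:
    sample_id: str
    morphology_call: str
    plastid_call: str
    its2_call: str


@dataclass(frozen=True)
class HybridVerdict:
    sample_id: str
    status: str  # parental | hybrid | ambiguous
    parental_taxon: Optional[str] = None
    maternal_parent: Optional[str] = None
    discordant_channels: tuple[str, ...] = ()
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.status == "hybrid" and self.maternal_parent is None:
            raise SpecError("hybrid verdict requires a maternal parent")
        if self.status == "parental" and self.discordant_channels:
            raise SpecError("parental verdict cannot list discordant channels")


# ---------------------------------------------------------------------------
# per-channel calls


def call_morphology(rec: MorphologyRecord) -> str:
    """Taxon from the four-field key.

    Long cylindrical inflorescences on plants over 30 cm are the tall
    terrestrial taxon; short ovoid inflorescences on short plants the
    aquatic one (flared ocreae reinforce but do not decide). Conflicting
    combinations are ambiguous.
    """
    if rec.inflorescence == "long_cylindrical" and rec.height == "over_30cm":
        return "coccinea"
    if rec.inflorescence == "short_ovoid" and rec.height == "under_30cm":
        return "stipulacea"
    return AMBIGUOUS


def call_its2_class(
    profile: HaplotypeProfile,
    refs: Optional[ReferenceProfileSet] = None,
    distance_cutoff: float = 0.5,
    type1: str = "Type1",
    us1: str = "US1",
) -> str:
    """ITS2 composition class from diagnostic rules, then nearest profile.

    Rules (checked on haplotypes present after noise filtering):
    exactly the two diagnostic haplotypes -> "stipulacea"; four or more
    haplotypes including both -> "coccinea_northern"; four or more lacking
    both -> "coccinea_southern". Anything else falls back to the nearest
    reference profile by Bray-Curtis dissimilarity on frequency vectors
    (tie or distance above ``distance_cutoff`` -> ambiguous). An empty
    profile is ambiguous ("no coverage").
    """
    if profile.no_coverage:
        return AMBIGUOUS
    present = set(profile.present_haplotypes(include_novel=True))
    has_diag = type1 in present and us1 in present
    lacks_diag = type1 not in present and us1 not in present
    if present == {type1, us1}:
        return "stipulacea"
    if len(present) >= 4 and has_diag:
        return "coccinea_northern"
    if len(present) >= 4 and lacks_diag:
        return "coccinea_southern"
    if not refs:
        return AMBIGUOUS
    names = sorted({n for ref in refs.values() for n in ref.frequencies} | present)
    freqs = profile.renormalized_frequencies(include_novel=True)
    vec = np.array([freqs.get(n, 0.0) for n in names])
    best: list[tuple[float, str]] = []
    for cls, ref in refs.items():
        rvec = np.array([ref.frequencies.get(n, 0.0) for n in names])
        best.append((float(braycurtis(vec, rvec)), cls))
    best.sort()
    if len(best) > 1 and abs(best[0][0] - best[1][0]) < 1e-12:
        return AMBIGUOUS
    if best[0][0] > distance_cutoff:
        return AMBIGUOUS
    return best[0][1]


# ---------------------------------------------------------------------------
# verdicts


def _to_taxon(label: str, taxon_a: str, taxon_b: str) -> str:
    """Collapse ITS2 class labels onto taxa (coccinea_* -> coccinea)."""
    if label == AMBIGUOUS:
        return AMBIGUOUS
    if label.startswith(taxon_b):
        return taxon_b
    if label.startswith(taxon_a):
        return taxon_a
    raise InputError(f"unknown taxon label {label!r}")


def classify_sample(
    ev: EvidenceBundle,
    taxon_a: str = "stipulacea",
    taxon_b: str = "coccinea",
    maternal_from_plastid: bool = True,
) -> HybridVerdict:
    """Combine the three evidence channels into a verdict.

    Any disagreement among determinate channels means hybrid, with the
    maternal parent read off the plastid (maternal plastid inheritance;
    switch ``maternal_from_plastid`` off for paternally inherited
    plastids). Channels calling ambiguous are excluded: if the remaining
    determinate calls agree the verdict is parental, flagged low-confidence
    when fewer than all three channels contributed. Discordance that rests
    on an ambiguous plastid cannot name a maternal parent and stays
    ambiguous.
    """
    calls = {
        "morphology": _to_taxon(ev.morphology_call, taxon_a, taxon_b),
        "plastid": _to_taxon(ev.plastid_call, taxon_a, taxon_b),
        "its2": _to_taxon(ev.its2_call, taxon_a, taxon_b),
    }
    determinate = {ch: c for ch, c in calls.items() if c != AMBIGUOUS}
    if not determinate:
        return HybridVerdict(sample_id=ev.sample_id, status=AMBIGUOUS)
    values = set(determinate.values())
    if len(values) == 1:
        taxon = values.pop()
        return HybridVerdict(
            sample_id=ev.sample_id,
            status="parental",
            parental_taxon=taxon,
            low_confidence=len(determinate) < 3,
        )
    if calls["plastid"] == AMBIGUOUS:
        return HybridVerdict(sample_id=ev.sample_id, status=AMBIGUOUS)
    # minority channels are the discordant ones; a 1-1 split lists both
    tally: dict[str, int] = {}
    for c in determinate.values():
        tally[c] = tally.get(c, 0) + 1
    min_count = min(tally.values())
    max_count = max(tally.values())
    discordant = tuple(
        ch
        for ch, c in determinate.items()
        if tally[c] == min_count or min_count == max_count
    )
    maternal = determinate["plastid"] if maternal_from_plastid else None
    return HybridVerdict(
        sample_id=ev.sample_id,
        status="hybrid",
        maternal_parent=maternal,
        discordant_channels=discordant,
    )


def cohort_report(
    verdicts: Sequence[HybridVerdict],
    evidence: Optional[Sequence[EvidenceBundle]] = None,
    out_path=None,
) -> pd.DataFrame:
    """One row per sample: channel calls, verdict, maternal parent.

    When written to TSV a '#'-prefixed footer summarises counts per
    status. Rows are emitted in input order; the content is input-order
    invariant apart from that ordering.
    """
    if not verdicts:
        raise SpecError("cohort_report needs at least one verdict")
    ev_by_id = {e.sample_id: e for e in evidence} if evidence else {}
    rows = []
    for v in verdicts:
        e = ev_by_id.get(v.sample_id)
        rows.append(
            {
                "sample": v.sample_id,
                "morphology": e.morphology_call if e else "",
                "plastome": e.plastid_call if e else "",
                "its2": e.its2_call if e else "",
                "verdict": v.status,
                "parental_taxon": v.parental_taxon or "",
                "maternal_parent": v.maternal_parent or "",
                "discordant_channels": ",".join(v.discordant_channels),
                "low_confidence": v.low_confidence,
            }
        )
    df = pd.DataFrame(rows)
    if out_path is not None:
        out_path = Path(out_path)
        counts = df["verdict"].value_counts().to_dict()
        with open(out_path, "w") as out:
            df.to_csv(out, sep="\t", index=False)
            out.write(f"# total\t{len(df)}\n")
            for status in ("parental", "hybrid", AMBIGUOUS):
                out.write(f"# {status}\t{counts.get(status, 0)}\n")
    return df
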