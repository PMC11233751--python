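"""End-to-end wiring of the simulation, tallying, marker and verdict stages.

These wrappers exist so that examples, the CLI and acceptance checks all
exercise one code path; each stage remains independently usable.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import pandas as pd

from . import simulate
from .classify import (
    EvidenceBundle,
    HybridVerdict,
    MorphologyRecord,
    ReferenceProfile,
    ReferenceProfileSet,
    call_its2_class,
    call_morphology,
    classify_sample,
    cohort_report,
)
from .errors import SpecError
from .its2 import HaplotypeCatalog, HaplotypeProfile, assign_names, tally
from .markers import (
    GenotypeCall,
    IgsRegion,
    PrimerPair,
    derive_igs,
    design_primer_pair,
    genotype,
    in_silico_pcr,
    rank_markers,
)
from .simulate import CohortResult, SimulationSpec

__all__ = [
    "its2_library",
    "MarkerAssay",
    "build_marker_assay",
    "genotype_template",
    "CohortRun",
    "run_cohort",
    "default_reference_profiles",
]


def its2_library(
    spec: SimulationSpec,
    sample_id: str = "sample",
    min_count: int = 2,
    min_freq: float = 0.005,
):
    """Simulate one library and tally it: returns (profile, truth, catalog).

    The single-sample analogue of the full pipeline: reference + window,
    haplotype catalog, paired reads, anchored tally, catalog naming.
    """
    reference, window = simulate.make_nrdna_reference(spec)
    catalog = simulate.make_haplotypes(
        reference.residues[window.start : window.end],
        n=spec.n_haplotypes,
        subs=spec.substitutions_per_haplotype,
        seed=spec.seed,
    )
    r1, r2, truth = simulate.simulate_reads(
        reference, window, catalog, spec, sample_id=sample_id
    )
    result = tally((r1, r2), window, min_count=min_count, min_freq=min_freq)
    profile = assign_names(result, catalog, sample_id=sample_id)
    return profile, truth, catalog


@dataclass
class MarkerAssay:
    """A ranked, primered marker with its expected product sizes."""

    region: IgsRegion
    primers: PrimerPair
    expected_a: int
    expected_b: int

    @property
    def expected(self) -> tuple[int, int]:
        return (self.expected_a, self.expected_b)


def build_marker_assay(
    genome_a, features_a, genome_b, features_b, top_k: int = 2
) -> list[MarkerAssay]:
    """Rank IGS regions by size difference and design assays for the top k.

    For each selected region, primers conserved between the genomes are
    placed in the flanking genes and the expected product length on each
    genome is predicted by in-silico PCR on that genome.
    """
    igs_a = derive_igs(features_a, len(genome_a))
    igs_b = derive_igs(features_b, len(genome_b))
    ranked = rank_markers(igs_a, igs_b, top_k=top_k)
    assays = []
    for region in ranked:
        primers = design_primer_pair(
            genome_a, genome_b, region.interval_a, region.interval_b
        )
        prods_a = in_silico_pcr(genome_a, primers)
        prods_b = in_silico_pcr(genome_b, primers)
        if not prods_a or not prods_b:
            raise SpecError(
                f"designed primers for {region.name!r} yield no product"
            )
        assays.append(
            MarkerAssay(
                region=region,
                primers=primers,
                expected_a=prods_a[0].length,
                expected_b=prods_b[0].length,
            )
        )
    return assays


def genotype_template(
    template, assays: Sequence[MarkerAssay], sample_id: str = "sample"
) -> list[GenotypeCall]:
    """Run every assay on one template and call each marker."""
    calls = []
    for assay in assays:
        products = in_silico_pcr(template, assay.primers)
        calls.append(
            genotype(
                [p.length for p in products],
                assay.expected,
                sample_id=sample_id,
                marker=assay.region.name,
            )
        )
    return calls


def default_reference_profiles() -> ReferenceProfileSet:
    """Reference ITS2 compositions matching the cohort generator's classes."""
    return ReferenceProfileSet(
        {
            "stipulacea": ReferenceProfile(
                frequencies=simulate.STATUS_MIXTURES["parental_A"],
                diagnostic_present=frozenset({"Type1", "US1"}),
            ),
            "coccinea_northern": ReferenceProfile(
                frequencies=simulate.STATUS_MIXTURES["parental_B"],
                diagnostic_present=frozenset({"Type1", "US1"}),
            ),
            "coccinea_southern": ReferenceProfile(
                frequencies=simulate.SOUTHERN_MIXTURE,
                diagnostic_absent=frozenset({"Type1", "US1"}),
            ),
        }
    )


@dataclass
class CohortRun:
    cohort: CohortResult
    profiles: dict[str, HaplotypeProfile]
    evidence: list[EvidenceBundle]
    verdicts: list[HybridVerdict]
    report: pd.DataFrame

    @property
    def metrics(self) -> dict[str, float]:
        """Sensitivity / false-positive rate / maternal accuracy vs truth."""
        truth_by_id = {t.sample_id: t for t in self.cohort.truth}
        tp = fn = fp = tn = 0
        maternal_ok = maternal_total = 0
        plastid_taxon = {"A": "stipulacea", "B": "coccinea"}
        for v in self.verdicts:
            truth = truth_by_id[v.sample_id]
            is_hybrid_true = truth.status == "hybrid"
            is_hybrid_called = v.status == "hybrid"
            if is_hybrid_true and is_hybrid_called:
                tp += 1
                maternal_total += 1
                if v.maternal_parent == plastid_taxon[truth.plastid_type]:
                    maternal_ok += 1
            elif is_hybrid_true:
                fn += 1
            elif is_hybrid_called:
                fp += 1
            else:
                tn += 1
        return {
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "false_positive_rate": fp / (fp + tn) if fp + tn else float("nan"),
            "maternal_accuracy": (
                maternal_ok / maternal_total if maternal_total else float("nan")
            ),
        }


def run_cohort(
    sheet: Sequence[tuple],
    spec: SimulationSpec,
    min_count: int = 2,
    min_freq: float = 0.005,
    refs: Optional[ReferenceProfileSet] = None,
) -> CohortRun:
    """Simulate a cohort and classify every sample end to end.

    Reads are tallied per sample; the plastid channel comes from in-silico
    PCR of the top-ranked IGS markers on the sample's true plastome type;
    morphology comes from the generated sheet. Verdicts and a table-style
    report are returned with recovery metrics against the truth table.
    """
    if refs is None:
        refs = default_reference_profiles()
    cohort = simulate.simulate_cohort(sheet, spec)
    if not cohort.truth:
        return CohortRun(
            cohort=cohort,
            profiles={},
            evidence=[],
            verdicts=[],
            report=pd.DataFrame(),
        )
    genome_a, genome_b, (features_a, features_b), _ = simulate.make_plastome_pair(spec)
    assays = build_marker_assay(genome_a, features_a, genome_b, features_b, top_k=2)
    templates = {"A": genome_a, "B": genome_b}
    plastid_taxon = {"A": "stipulacea", "B": "coccinea"}
    morph_by_id = {
        row["sample"]: MorphologyRecord(
            sample_id=row["sample"],
            inflorescence=row["inflorescence"],
            flared_ocreae=bool(row["flared_ocreae"]),
            leaf_shape=row["leaf_shape"],
            height=row["height"],
        )
        for row in cohort.morphology.to_dict("records")
    }
    profiles: dict[str, HaplotypeProfile] = {}
    evidence: list[EvidenceBundle] = []
    verdicts: list[HybridVerdict] = []
    for sample in cohort.truth:
        r1, r2 = cohort.reads[sample.sample_id]
        result = tally((r1, r2), cohort.window, min_count=min_count, min_freq=min_freq)
        profile = assign_names(result, cohort.catalog, sample_id=sample.sample_id)
        profiles[sample.sample_id] = profile
        its2_call = call_its2_class(profile, refs)
        calls = genotype_template(
            templates[sample.plastid_type], assays, sample_id=sample.sample_id
        )
        determinate = {c.call for c in calls if c.call in ("A", "B")}
        if len(determinate) == 1:
            plastid_call = plastid_taxon[determinate.pop()]
        else:
            plastid_call = "ambiguous"
        ev = EvidenceBundle(
            sample_id=sample.sample_id,
            morphology_call=call_morphology(morph_by_id[sample.sample_id]),
            plastid_call=plastid_call,
            its2_call=its2_call,
        )
        evidence.append(ev)
        verdicts.append(classify_sample(ev))
    report = cohort_report(verdicts, evidence)
    return CohortRun(
        cohort=cohort,
        profiles=profiles,
        evidence=evidence,
        verdicts=verdicts,
        report=report,
    )
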