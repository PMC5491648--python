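"""Seeded synthetic-data generators.

Every generator is a deterministic function of (configuration, seed).  The
root seed is split into fixed per-generator child streams
(:func:`_rng`), so adding a generator never perturbs existing streams.

The default :class:`StudyDesign` emulates the screening experiment the
analyses assume: 4 wheat genotypes × 2 tissues × 2 treatments (0 vs 200 mM
NaCl) × 3 replicates, with genotype-specific multiplicative treatment effects
on each physio-biochemical indicator and Gaussian measurement noise.  The
default effect sizes follow the reported contrasts (e.g. 56–78% shoot
dry-matter reduction, up to 60% MDA increase in the sensitive genotype,
120–166% proline increase in shoot), ordered Kharchia-65 > KRL-210 >
WH-542 > HD-2329 in tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from saltphen.methylome import CloneSet, classify_context

__all__ = [
    "IndicatorSim",
    "StudyDesign",
    "MethylomeScenario",
    "default_design",
    "DEFAULT_TRUE_RATIOS",
    "gen_assay_dataset",
    "gen_reference",
    "gen_bisulfite_clones",
    "gen_ct_table",
]

# fixed spawn keys: one independent child stream per generator
_STREAMS = {"assay": 0, "reference": 1, "clones": 2, "ct": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class IndicatorSim:
    """Generating parameters for one assay × tissue indicator.

    ``effect`` maps genotype → multiplicative treatment effect on the control
    mean (1.0 = no effect); ``noise_sd`` is the Gaussian SD on the
    measurement scale.
    """

    assay: str
    tissue: str
    control_mean: float
    effect: Mapping[str, float]
    noise_sd: float

    def __post_init__(self) -> None:
        if self.control_mean <= 0:
            raise ValueError("control mean must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if any(m <= 0 for m in self.effect.values()):
            raise ValueError("effect multipliers must be > 0")


@dataclass(frozen=True)
class StudyDesign:
    genotypes: tuple[str, ...]
    indicators: tuple[IndicatorSim, ...]
    treatments: tuple[str, str] = ("control", "salt")
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per cell")
        for ind in self.indicators:
            missing = set(self.genotypes) - set(ind.effect)
            if missing:
                raise ValueError(
                    f"{ind.assay}/{ind.tissue}: no effect for genotypes {sorted(missing)}"
                )

    def with_noise(self, scale: float) -> "StudyDesign":
        """Copy of the design with every noise SD multiplied by ``scale``."""
        return replace(
            self,
            indicators=tuple(
                replace(i, noise_sd=i.noise_sd * scale) for i in self.indicators
            ),
        )


GENOTYPES = ("KRL-210", "Kharchia-65", "HD-2329", "WH-542")

# Genotype-specific treatment multipliers per indicator, tolerance-ordered
# Kharchia-65 > KRL-210 > WH-542 > HD-2329.  Keys: (assay, tissue).
_DEFAULT_EFFECTS: dict[tuple[str, str], tuple[float, dict[str, float]]] = {
    # (assay, tissue): (control_mean, {genotype: multiplier})
    ("dry_weight", "shoot"): (2.5, {"Kharchia-65": 0.44, "KRL-210": 0.38, "WH-542": 0.28, "HD-2329": 0.22}),
    ("dry_weight", "root"): (1.0, {"Kharchia-65": 0.80, "KRL-210": 0.78, "WH-542": 0.74, "HD-2329": 0.72}),
    ("proline", "shoot"): (4.0, {"Kharchia-65": 2.66, "KRL-210": 2.50, "WH-542": 2.35, "HD-2329": 2.20}),
    ("proline", "root"): (4.0, {"Kharchia-65": 1.10, "KRL-210": 1.07, "WH-542": 1.04, "HD-2329": 1.01}),
    ("soluble_sugar", "shoot"): (50.0, {"Kharchia-65": 1.25, "KRL-210": 1.15, "WH-542": 0.95, "HD-2329": 0.85}),
    ("soluble_sugar", "root"): (65.0, {"Kharchia-65": 0.74, "KRL-210": 0.71, "WH-542": 0.68, "HD-2329": 0.64}),
    ("tpc", "shoot"): (2.5, {"Kharchia-65": 1.35, "KRL-210": 1.24, "WH-542": 1.12, "HD-2329": 1.02}),
    ("tpc", "root"): (2.0, {"Kharchia-65": 1.33, "KRL-210": 1.22, "WH-542": 1.10, "HD-2329": 1.01}),
    ("mda", "shoot"): (20.0, {"Kharchia-65": 1.05, "KRL-210": 1.10, "WH-542": 1.40, "HD-2329": 1.60}),
    ("mda", "root"): (12.0, {"Kharchia-65": 1.03, "KRL-210": 1.06, "WH-542": 1.25, "HD-2329": 1.35}),
    ("antioxidant", "shoot"): (55.0, {"Kharchia-65": 1.30, "KRL-210": 1.26, "WH-542": 1.08, "HD-2329": 1.02}),
    ("antioxidant", "root"): (52.0, {"Kharchia-65": 1.28, "KRL-210": 1.24, "WH-542": 1.07, "HD-2329": 1.02}),
    ("na_k_ratio", "shoot"): (0.2, {"Kharchia-65": 1.30, "KRL-210": 1.40, "WH-542": 1.70, "HD-2329": 1.80}),
    ("na_k_ratio", "root"): (0.5, {"Kharchia-65": 1.20, "KRL-210": 1.30, "WH-542": 1.50, "HD-2329": 1.60}),
    ("total_chlorophyll", "leaf"): (2.0, {"Kharchia-65": 0.98, "KRL-210": 0.85, "WH-542": 0.81, "HD-2329": 0.74}),
}


def default_design(noise_cv: float = 0.05) -> StudyDesign:
    """The shipped 4-genotype × 15-indicator design.

    ``noise_cv`` sets each indicator's Gaussian SD as a fraction of its
    control mean (default 5%, in line with replicate scatter of bench
    assays); 0 gives a deterministic design.
    """
    indicators = tuple(
        IndicatorSim(assay, tissue, mean, dict(effects), noise_sd=mean * noise_cv)
        for (assay, tissue), (mean, effects) in _DEFAULT_EFFECTS.items()
    )
    return StudyDesign(genotypes=GENOTYPES, indicators=indicators)


def gen_assay_dataset(design: StudyDesign, seed: int = 0) -> pd.DataFrame:
    """Tidy replicate-level assay table.

    value = control_mean × (1 if control else effect[genotype]) + N(0, SD).
    Columns: sample_id, genotype, tissue, treatment, replicate, assay, value.
    """
    rng = _rng(seed, "assay")
    rows = []
    for ind in design.indicators:
        for genotype in design.genotypes:
            for treatment in design.treatments:
                mult = 1.0 if treatment == design.treatments[0] else ind.effect[genotype]
                mean = ind.control_mean * mult
                for rep in range(1, design.replicates + 1):
                    value = mean + rng.normal(0.0, ind.noise_sd) if ind.noise_sd else mean
                    rows.append(
                        {
                            "sample_id": f"{genotype}_{ind.tissue}_{treatment}_r{rep}",
                            "genotype": genotype,
                            "tissue": ind.tissue,
                            "treatment": treatment,
                            "replicate": rep,
                            "assay": ind.assay,
                            "value": value,
                        }
                    )
    return pd.DataFrame(rows)


def gen_reference(length: int, gc_fraction: float = 0.45, seed: int = 0) -> str:
    """Random reference amplicon with i.i.d. bases at the given GC fraction.

    For length >= 50 the draw is repeated (bounded) until the sequence
    contains at least one cytosine in each of the CG, CHG and CHH contexts,
    so downstream context summaries are never vacuous.
    """
    if length < 3:
        raise ValueError("length must be >= 3")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = _rng(seed, "reference")
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    bases = np.array(["A", "C", "G", "T"])
    for _ in range(100):
        seq = "".join(rng.choice(bases, size=length, p=p))
        if length < 50:
            return seq
        contexts = {
            classify_context(seq, i) for i, b in enumerate(seq) if b == "C"
        }
        if {"CG", "CHG", "CHH"} <= contexts:
            return seq
    raise RuntimeError("could not generate a reference with all three contexts")


@dataclass(frozen=True)
class MethylomeScenario:
    """Generating parameters for one bisulfite clone set.

    ``p_cg``/``p_chg``/``p_chh`` are the per-cytosine methylation
    probabilities by context; ``conversion_efficiency`` is the probability
    that an unmethylated C is read as T (failed conversions read as C).
    Clone count defaults to the 10 sequenced clones per sample.
    """

    p_cg: float
    p_chg: float
    p_chh: float
    n_clones: int = 10
    conversion_efficiency: float = 1.0
    genotype: str = "synthetic"
    tissue: str = "shoot"
    treatment: str = "control"

    def __post_init__(self) -> None:
        for name in ("p_cg", "p_chg", "p_chh"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.conversion_efficiency <= 1:
            raise ValueError("conversion efficiency must be in (0, 1]")
        if self.n_clones < 1:
            raise ValueError("need >= 1 clone")

    def prob(self, context: str) -> float:
        return {"CG": self.p_cg, "CHG": self.p_chg, "CHH": self.p_chh}.get(
            context, self.p_chh
        )


def gen_bisulfite_clones(
    reference: str, scenario: MethylomeScenario, seed: int = 0
) -> CloneSet:
    """Simulate bisulfite-converted clone reads of ``reference``.

    Per clone and reference cytosine: methylated (stays C) with the context's
    probability; otherwise converted C→T with probability
    ``conversion_efficiency`` (a failed conversion reads as C).  Cytosines of
    unknown context use the CHH probability.  Non-cytosine bases are copied
    verbatim (no sequencing errors or indels are simulated).
    """
    rng = _rng(seed, "clones")
    ref = reference.upper()
    c_positions = [i for i, b in enumerate(ref) if b == "C"]
    clones = []
    for _ in range(scenario.n_clones):
        out = list(ref)
        for pos in c_positions:
            p_meth = scenario.prob(classify_context(ref, pos))
            if rng.random() < p_meth:
                continue  # methylated: protected from conversion
            if rng.random() < scenario.conversion_efficiency:
                out[pos] = "T"
        clones.append("".join(out))
    return CloneSet(
        scenario.genotype, scenario.tissue, scenario.treatment, tuple(clones)
    )


# Shoot fold changes reported for the two HKT2 transporters (ratio scale:
# <1 = downregulated under salt), used as the default qPCR scenario.
DEFAULT_TRUE_RATIOS: dict[str, dict[tuple[str, str], float]] = {
    "TaHKT2;1": {
        ("Kharchia-65", "shoot"): 1 / 4.05,
        ("KRL-210", "shoot"): 1 / 3.21,
        ("WH-542", "shoot"): 4.52,
        ("HD-2329", "shoot"): 6.05,
    },
    "TaHKT2;3": {
        ("Kharchia-65", "shoot"): 1 / 8.05,
        ("KRL-210", "shoot"): 1 / 6.52,
        ("WH-542", "shoot"): 8.51,
        ("HD-2329", "shoot"): 10.30,
    },
}


def gen_ct_table(
    true_ratios: Mapping[str, Mapping[tuple[str, str], float]] = DEFAULT_TRUE_RATIOS,
    ct_noise_sd: float = 0.0,
    bio_reps: int = 3,
    tech_reps: int = 3,
    reference_gene: str = "actin",
    reference_ct: float = 20.0,
    target_control_ct: float = 26.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table realizing designated expression ratios.

    ``true_ratios`` maps gene → {(genotype, tissue): ratio}, ratio being the
    treated/control expression ratio (2^(−ΔΔCt)); the treated target Ct is
    offset by −log2(ratio).  Gaussian noise of SD ``ct_noise_sd`` is added to
    every well.  At zero noise the ΔΔCt analysis recovers each ratio exactly.
    """
    if any(r <= 0 for gene in true_ratios.values() for r in gene.values()):
        raise ValueError("expression ratios must be > 0")
    rng = _rng(seed, "ct")
    rows = []

    def emit(genotype, tissue, treatment, gene, base_ct):
        for b in range(1, bio_reps + 1):
            for t in range(1, tech_reps + 1):
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd else 0.0
                rows.append(
                    {
                        "genotype": genotype,
                        "tissue": tissue,
                        "treatment": treatment,
                        "gene_name": gene,
                        "bio_rep": b,
                        "tech_rep": t,
                        "ct": base_ct + noise,
                    }
                )

    cells = sorted({cell for gene in true_ratios.values() for cell in gene})
    for genotype, tissue in cells:
        for treatment in ("control", "salt"):
            emit(genotype, tissue, treatment, reference_gene, reference_ct)
    for gene, cells_map in true_ratios.items():
        for (genotype, tissue), ratio in cells_map.items():
            emit(genotype, tissue, "control", gene, target_control_ct)
            emit(genotype, tissue, "salt", gene, target_control_ct - np.log2(ratio))
    return pd.DataFrame(rows)
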