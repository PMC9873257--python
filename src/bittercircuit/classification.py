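"""Group statistics and effect-strength classification across genotypes.

For each behavior, an experimental driver line is compared against two
genetic controls (driver-only and effector-only) at three light intensities,
and the effect strength is expressed relative to a reference line labeling
the entire bitter-sensing population:

1. *Gate*: a one-way ANOVA across the genotype × intensity cells of the
   behavior asks whether the manipulation has an effect at any intensity.
2. *Effect size*: per intensity, the experimental mean is compared with each
   control mean and the smaller of the two differences (in magnitude) is the
   effect; if the two control comparisons disagree in sign the effect is 0.
3. *Classification*: the maximal effect over intensities, normalized by the
   reference line's maximal effect, is classed as strong (>= 80%), moderate
   (>= 40%), or weak (significant but < 40%); a failed gate yields "none".

Dunnett's many-to-one test (experimental vs each control, family-wise error
controlled) backs the per-comparison significance reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
STRONG_THRESHOLD = 0.8
MODERATE_THRESHOLD = 0.4


@dataclass
class AnovaResult:
    F: float
    p: float
    significant: bool


@dataclass
class EffectRecord:
    behavior: str
    genotype: str
    gate_p: float
    effect: float
    normalized_effect: float
    effect_class: str  # strong | moderate | weak | none


def anova_gate(groups: Sequence[np.ndarray], alpha: float = ALPHA) -> AnovaResult:
    """One-way ANOVA across measurement cells; the significance gate.

    Degenerate input (every value identical across all groups, so zero
    within- and between-group variance) is reported as F=0, p=1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:
        return AnovaResult(F=0.0, p=1.0, significant=False)
    f, p = stats.f_oneway(*groups)
    if math.isnan(f):  # zero within-group variance but distinct means
        f, p = math.inf, 0.0
    return AnovaResult(F=float(f), p=float(p), significant=bool(p < alpha))


def dunnett_compare(
    experimental: np.ndarray,
    controls: Sequence[np.ndarray],
    random_state: int = 1234,
) -> np.ndarray:
    """Two-sided many-to-one adjusted p-values, experimental vs each control.

    The experimental group is shared across comparisons, so it plays the role
    of Dunnett's common reference; family-wise error is controlled over the
    set of controls. With a single control this reduces to an unadjusted
    two-sample t-test. The adjusted p is computed by randomized integration
    of the multivariate t distribution, so a fixed ``random_state`` keeps
    results reproducible.
    """
    experimental = np.asarray(experimental, dtype=float)
    controls = [np.asarray(c, dtype=float) for c in controls]
    if not controls:
        raise ValueError("at least one control group required")
    if len(controls) == 1:
        return np.array([stats.ttest_ind(controls[0], experimental).pvalue])
    res = stats.dunnett(
        *controls, control=experimental, random_state=np.random.default_rng(random_state)
    )
    return np.asarray(res.pvalue)


def effect_size(
    experimental: np.ndarray,
    control_1: np.ndarray,
    control_2: np.ndarray,
) -> float:
    """Conservative effect estimate vs two controls.

    The experimental mean is compared with each control mean and the smaller
    difference (in magnitude) is returned, signed by the shared direction.
    If the controls straddle the experimental mean (the two comparisons
    disagree in sign) no consistent effect exists and 0 is returned.
    """
    d1 = float(np.mean(experimental) - np.mean(control_1))
    d2 = float(np.mean(experimental) - np.mean(control_2))
    if d1 == 0 or d2 == 0:
        return 0.0
    if math.copysign(1, d1) != math.copysign(1, d2):
        return 0.0
    return math.copysign(min(abs(d1), abs(d2)), d1)


def classify_effect(
    effects_by_intensity: Sequence[float],
    reference_max: float,
    gate: AnovaResult,
    behavior: str = "",
    genotype: str = "",
) -> EffectRecord:
    """Class label from the maximal effect across intensities.

    ``normalized_effect`` = max |effect| over intensities / |reference_max|,
    where ``reference_max`` is the maximal effect of the reference (whole
    bitter population) line for the same behavior. Thresholds: strong >= 0.8,
    moderate >= 0.4, weak below that (when the gate passes); a failed gate is
    "none" regardless of magnitude. A zero reference is undefined (NaN).
    """
    magnitudes = [abs(e) for e in effects_by_intensity]
    best = max(magnitudes) if magnitudes else 0.0
    signed = max(effects_by_intensity, key=abs) if effects_by_intensity else 0.0
    if reference_max == 0:
        normalized = math.nan
    else:
        normalized = best / abs(reference_max)
    if not gate.significant:
        cls = "none"
    elif math.isnan(normalized):
        cls = "undefined"
    elif normalized >= STRONG_THRESHOLD:
        cls = "strong"
    elif normalized >= MODERATE_THRESHOLD:
        cls = "moderate"
    else:
        cls = "weak"
    return EffectRecord(
        behavior=behavior,
        genotype=genotype,
        gate_p=gate.p,
        effect=signed,
        normalized_effect=normalized,
        effect_class=cls,
    )


def classify_table(
    df: pd.DataFrame,
    experimental: str,
    controls: tuple[str, str],
    reference: str,
    reference_controls: tuple[str, str] | None = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Run the full gate → effect → classification pipeline on a long table.

    ``df`` has columns (behavior, genotype, intensity, value); one row per
    trial. For each behavior, the gate ANOVA pools all genotype × intensity
    cells of the experimental genotype and its controls, the per-intensity
    effect is the min-of-two-controls difference, and the reference maximal
    effect is computed the same way for the reference genotype (against its
    own controls, defaulting to the same control labels).
    """
    required = {"behavior", "genotype", "intensity", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"measurement table needs columns {sorted(required)}")
    reference_controls = reference_controls or controls
    records = []
    for behavior, sub in df.groupby("behavior", sort=True):
        ref_effects = _effects_by_intensity(sub, reference, reference_controls)
        reference_max = max((abs(e) for e in ref_effects), default=0.0)
        cells = [
            g["value"].to_numpy()
            for (_, _), g in sub[
                sub["genotype"].isin([experimental, *controls])
            ].groupby(["genotype", "intensity"], sort=True)
        ]
        gate = anova_gate(cells, alpha=alpha)
        effects = _effects_by_intensity(sub, experimental, controls)
        records.append(
            classify_effect(effects, reference_max, gate, behavior=behavior, genotype=experimental)
        )
    return pd.DataFrame([r.__dict__ for r in records])


def _effects_by_intensity(
    sub: pd.DataFrame, genotype: str, controls: tuple[str, str]
) -> list[float]:
    effects = []
    for intensity, cell in sub.groupby("intensity", sort=True):
        groups = {
            g: cell[cell["genotype"] == g]["value"].to_numpy()
            for g in (genotype, *controls)
        }
        if any(len(v) == 0 for v in groups.values()):
            continue
        effects.append(
            effect_size(groups[genotype], groups[controls[0]], groups[controls[1]])
        )
    return effects
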