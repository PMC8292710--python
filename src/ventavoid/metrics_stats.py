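"""DVH and functional-DVH metrics, NTCP toxicity estimates, group statistics.

``Dx`` follows the sorted-voxel rule (minimum dose received by the hottest
x% of the structure volume, computed from the un-binned voxel doses), and
``Vx`` is exact counting of voxels at or above x Gy. The conformity index is
prescription-isodose volume over target volume; the homogeneity index is
D5/D95.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

# number of simultaneously tested metric families used for the Bonferroni
# correction; 25 yields a corrected alpha of 0.002 at alpha = 0.05
DEFAULT_FAMILY_SIZE = 25


# --------------------------------------------------------------------------
# DVH
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DVH:
    structure: str
    edges_gy: np.ndarray
    volume_pct: np.ndarray
    n_voxels: int
    mean_gy: float
    max_gy: float

    def volume_at(self, dose_gy: float) -> float:
        """Cumulative volume (%) receiving at least ``dose_gy``, from bins."""
        i = int(np.searchsorted(self.edges_gy, dose_gy, side="left"))
        return float(self.volume_pct[min(i, len(self.volume_pct) - 1)])


def _masked_doses(dose, mask: np.ndarray | None) -> np.ndarray:
    if hasattr(dose, "spacing") and hasattr(dose, "data"):
        arr = dose.data          # ImageGrid
    else:
        arr = np.asarray(dose, dtype=np.float64)
    if mask is not None:
        arr = arr[np.asarray(mask, dtype=bool)]
    return np.ravel(arr)


def cumulative_dvh(dose, mask: np.ndarray | None = None, bin_width_gy: float = 0.1,
                   structure: str = "") -> DVH:
    """Cumulative dose-volume histogram with fixed-width bins.

    Mean and max are exact (un-binned).
    """
    doses = _masked_doses(dose, mask)
    if doses.size == 0:
        raise ValueError("structure mask is empty")
    top = float(doses.max())
    edges = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
    volume = np.array([100.0 * np.mean(doses >= e) for e in edges])
    return DVH(structure=structure, edges_gy=edges, volume_pct=volume,
               n_voxels=doses.size, mean_gy=float(doses.mean()),
               max_gy=top)


def _parse_metric(spec) -> tuple[str, float | None]:
    if isinstance(spec, tuple):
        kind, value = spec
        return str(kind), float(value)
    s = str(spec).strip()
    if s in ("mean", "max"):
        return s, None
    if s.upper() == "D5-D95":
        return "D5-D95", None
    if s[0] in "DVdv":
        return s[0].upper(), float(s[1:])
    raise ValueError(f"unrecognized DVH metric spec {spec!r}")


def dvh_metric(dose, spec, mask: np.ndarray | None = None) -> float:
    """Evaluate a DVH metric from voxel doses.

    ``spec``: ``"mean"``, ``"max"``, ``"Vx"`` (% volume >= x Gy), ``"Dx"``
    (minimum dose of the hottest x% of voxels), ``"D5-D95"``, or the tuple
    forms ``("V", x)`` / ``("D", x)``.
    """
    doses = _masked_doses(dose, mask)
    if doses.size == 0:
        raise ValueError("structure mask is empty")
    kind, value = _parse_metric(spec)
    if kind == "mean":
        return float(doses.mean())
    if kind == "max":
        return float(doses.max())
    if kind == "V":
        return 100.0 * float(np.mean(doses >= value))
    if kind == "D":
        if not (0.0 < value <= 100.0):
            raise ValueError(f"Dx percentage must be in (0, 100], got {value}")
        ordered = np.sort(doses)[::-1]
        k = int(math.ceil(value / 100.0 * doses.size))
        return float(ordered[k - 1])
    if kind == "D5-D95":
        return dvh_metric(doses, ("D", 5.0)) - dvh_metric(doses, ("D", 95.0))
    raise ValueError(f"unrecognized DVH metric spec {spec!r}")


def conformity_index(dose, ctv_mask: np.ndarray, rx_gy: float,
                     body_mask: np.ndarray | None = None) -> float:
    """Prescription-isodose volume over target volume."""
    if rx_gy <= 0:
        raise ValueError("prescription must be positive")
    ctv_mask = np.asarray(ctv_mask, dtype=bool)
    if not np.any(ctv_mask):
        raise ValueError("target mask is empty")
    arr = dose.data if hasattr(dose, "spacing") else np.asarray(dose)
    if body_mask is not None:
        covered = int(np.sum((arr >= rx_gy) & np.asarray(body_mask, dtype=bool)))
    else:
        covered = int(np.sum(arr >= rx_gy))
    return covered / int(np.sum(ctv_mask))


def homogeneity_index(dose, ctv_mask: np.ndarray) -> float:
    """D5 over D95 of the target."""
    d5 = dvh_metric(dose, ("D", 5.0), mask=ctv_mask)
    d95 = dvh_metric(dose, ("D", 95.0), mask=ctv_mask)
    if d95 <= 0:
        raise ValueError("target D95 is zero; homogeneity index undefined")
    return d5 / d95


# --------------------------------------------------------------------------
# NTCP
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NTCPModel:
    """Logistic toxicity model ``p = 1 / (1 + exp(-(b0 + b1 x)))``.

    Shipped default coefficients are placeholders (the published model's
    coefficients are not reproduced here); every report carries the
    provenance tag.
    """

    metric: str
    intercept: float
    slope: float
    endpoint: str = "grade2plus_rp"
    provenance: str = "non-paper-default"

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise ValueError("model coefficients must be finite")


def default_ntcp_models() -> dict[str, NTCPModel]:
    """Placeholder Grade 2+ pneumonitis models on fV20/fV30/fMLD.

    Chosen only to be monotone increasing with plausible mid-range
    probabilities; flagged ``non-paper-default``.
    """
    return {
        "fV20": NTCPModel("fV20", intercept=-2.4, slope=0.055),
        "fV30": NTCPModel("fV30", intercept=-2.1, slope=0.055),
        "fMLD": NTCPModel("fMLD", intercept=-2.6, slope=0.12),
    }


def ntcp_logistic(x: float, model: NTCPModel) -> float:
    return float(1.0 / (1.0 + np.exp(-(model.intercept + model.slope * x))))


@dataclass(frozen=True)
class NTCPReduction:
    metric: str
    delta: np.ndarray                # standard minus functional, per case
    mean: float
    range: tuple[float, float]
    provenance: str


def ntcp_reduction(standard: dict[str, np.ndarray], functional: dict[str, np.ndarray],
                   models: dict[str, NTCPModel] | None = None
                   ) -> dict[str, NTCPReduction]:
    """Absolute toxicity reduction ``p(standard) - p(functional)`` per metric."""
    models = models or default_ntcp_models()
    out: dict[str, NTCPReduction] = {}
    for metric, model in models.items():
        if metric not in standard or metric not in functional:
            continue
        s = np.atleast_1d(np.asarray(standard[metric], dtype=np.float64))
        f = np.atleast_1d(np.asarray(functional[metric], dtype=np.float64))
        if s.shape != f.shape:
            raise ValueError(f"unpaired input for metric {metric!r}")
        ps = np.array([ntcp_logistic(v, model) for v in s])
        pf = np.array([ntcp_logistic(v, model) for v in f])
        delta = ps - pf
        out[metric] = NTCPReduction(
            metric=metric, delta=delta, mean=float(delta.mean()),
            range=(float(delta.min()), float(delta.max())),
            provenance=model.provenance,
        )
    return out


# --------------------------------------------------------------------------
# group statistics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricComparison:
    metric: str
    anova_f: float
    anova_p: float
    ttests: dict[tuple[str, str], tuple[float, float, bool]]
    corrected_alpha: float


def corrected_alpha(alpha: float = 0.05, family_size: int = DEFAULT_FAMILY_SIZE
                    ) -> float:
    """Bonferroni-corrected significance level."""
    if family_size < 1:
        raise ValueError("family size must be >= 1")
    return alpha / family_size


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t; identical samples return (0, 1) instead of NaN."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D and the same length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    if np.allclose(a, b):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def compare_groups(metric_table: dict[str, dict[str, np.ndarray]],
                   pairs: list[tuple[str, str]] | None = None,
                   alpha: float = 0.05,
                   family_size: int = DEFAULT_FAMILY_SIZE
                   ) -> dict[str, MetricComparison]:
    """One-way ANOVA across groups and post-hoc paired t-tests per metric.

    ``metric_table[metric][group]`` holds per-case values; groups must be
    paired (same case order) for the t-tests. Flags are evaluated at the
    Bonferroni-corrected alpha.
    """
    alpha_c = corrected_alpha(alpha, family_size)
    out: dict[str, MetricComparison] = {}
    for metric, groups in metric_table.items():
        names = sorted(groups)
        samples = [np.asarray(groups[g], dtype=np.float64) for g in names]
        if len(samples) < 2 or any(len(s) < 2 for s in samples):
            raise ValueError(f"metric {metric!r} needs >= 2 groups of >= 2 values")
        if all(np.allclose(s, samples[0]) for s in samples[1:]):
            f_stat, p_anova = 0.0, 1.0
        else:
            f_stat, p_anova = stats.f_oneway(*samples)
        tests: dict[tuple[str, str], tuple[float, float, bool]] = {}
        for g1, g2 in pairs or [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]:
            t, p = paired_t(groups[g1], groups[g2])
            tests[(g1, g2)] = (t, p, p < alpha_c)
        out[metric] = MetricComparison(metric=metric, anova_f=float(f_stat),
                                       anova_p=float(p_anova), ttests=tests,
                                       corrected_alpha=alpha_c)
    return out
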