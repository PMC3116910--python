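"""Growth-curve phenotyping: fitness components and relative traits.

From one well's optical-density (OD) time series, three fitness components are
extracted (the study design samples every 20 min for 72 h):

* **lag** — population adaptation time: where the tangent through the
  steepest stretch of ln(OD) intersects the pre-growth baseline level;
* **rate** — population doubling time: ln(2) divided by the maximal
  sliding-window slope of ln(OD);
* **efficiency** — total change in population density: maximal smoothed OD
  minus the baseline OD.

Each strain measurement is then normalized to run-matched reference-strain
measurements into a log2 relative trait (positive = superior proliferation for
every component; the efficiency ratio is sign-flipped to keep that
directionality), and relative traits are assembled into a
:class:`~phenomap.containers.TraitMatrix`.

Input OD is treated as blank-corrected culture density (the instrument blank,
if any, is removed with the ``blank`` parameter before the log transform).  The
first-2h baseline (median by default) estimates the inoculum level; it anchors
the lag tangent-intercept and the efficiency origin but is *not* subtracted
before the log, because the baseline contains the inoculum and subtracting it
inflates the exponential-phase log-slope without bound.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import TraitMatrix, VARIABLES, trait_id

__all__ = [
    "GrowthCurve",
    "FitnessTriple",
    "RelativeTrait",
    "NormalizationPolicy",
    "extract_features",
    "compute_relative_trait",
    "build_trait_matrix",
    "replicate_cv",
]

#: Minimum number of samples for feature extraction.
MIN_POINTS = 10

#: Total density change below which a well is called "no growth" (OD units).
NO_GROWTH_OD = 0.05


@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD time series with its strain/environment/run identity."""

    strain_id: str
    environment_id: str
    run_id: str
    replicate: int
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)
        if times.ndim != 1 or od.shape != times.shape:
            raise ValueError("times and od must be 1-d arrays of equal length")
        if len(times) >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(od)):
            raise ValueError("od values must be finite")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class FitnessTriple:
    """Extracted fitness components for one well.

    ``lag`` and ``rate`` are in hours, ``efficiency`` in OD units; any of them
    is NaN when undefined (e.g. a non-growing well).  ``quality_flags``
    collects extraction warnings such as ``"no_growth"``.
    """

    lag: float
    rate: float
    efficiency: float
    quality_flags: frozenset = frozenset()

    @property
    def grew(self) -> bool:
        return "no_growth" not in self.quality_flags


def _sliding_ols(times: np.ndarray, y: np.ndarray, window: int):
    """Per-window OLS of y on t: slopes, intercepts and slope standard errors."""
    n = len(times) - window + 1
    slopes = np.full(n, np.nan)
    intercepts = np.full(n, np.nan)
    ses = np.full(n, np.nan)
    for i in range(n):
        t = times[i : i + window]
        yy = y[i : i + window]
        tm = t.mean()
        ym = yy.mean()
        sxx = np.sum((t - tm) ** 2)
        s = np.sum((t - tm) * (yy - ym)) / sxx
        a = ym - s * tm
        resid = yy - (a + s * t)
        slopes[i] = s
        intercepts[i] = a
        ses[i] = np.sqrt(np.sum(resid**2) / max(window - 2, 1) / sxx)
    return slopes, intercepts, ses


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinkage."""
    kernel = np.ones(window) / window
    num = np.convolve(x, kernel, mode="same")
    norm = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / norm


def extract_features(
    curve: GrowthCurve,
    window: int = 5,
    baseline_quantile: float = 0.5,
    baseline_window_h: float = 2.0,
    blank: float = 0.0,
    no_growth_od: float = NO_GROWTH_OD,
    floor_eps: float = 1e-4,
) -> FitnessTriple:
    """Extract (lag, rate, efficiency) from one growth curve.

    Parameters
    ----------
    curve
        The well's OD series; at least :data:`MIN_POINTS` samples.
    window
        Sliding-window length (samples, >= 3) for the ln(OD) slope regression
        and the OD smoothing used for efficiency.
    baseline_quantile
        Quantile of the first ``baseline_window_h`` hours taken as the
        baseline (inoculum) OD level; the default (median) is robust to
        measurement noise around the pre-growth plateau.
    blank
        Instrument/medium blank subtracted from OD before the log transform.
        Default 0 (input already blank-corrected).
    no_growth_od
        Detection floor: a total density change below this flags "no_growth"
        and leaves rate and lag undefined rather than reporting extreme values.
    """
    if len(curve) < MIN_POINTS:
        raise ValueError(
            f"need >= {MIN_POINTS} points for feature extraction, got {len(curve)}"
        )
    if window < 3:
        raise ValueError("window must be >= 3 points")
    times = curve.times
    od = curve.od - blank
    flags: set[str] = set()

    early = od[times <= times[0] + baseline_window_h]
    if len(early) == 0:
        early = od[:window]
    baseline = float(np.quantile(early, baseline_quantile))
    baseline = max(baseline, floor_eps)

    smoothed = _smooth(od, window)
    efficiency = float(np.max(smoothed) - baseline)
    if efficiency < no_growth_od:
        flags.add("no_growth")
        return FitnessTriple(np.nan, np.nan, max(efficiency, 0.0), frozenset(flags))

    # Slopes of ln(OD) on the smoothed series; candidate windows must sit
    # clearly above the baseline — relative to both the inoculum level and
    # the measured pre-growth noise — so plateau noise cannot masquerade as
    # exponential growth.
    y = np.log(np.maximum(smoothed, floor_eps))
    noise = float(np.std(early)) if len(early) > 2 else 0.0
    min_level = baseline + max(0.25 * baseline, 5.0 * noise)
    slopes, intercepts, ses = _sliding_ols(times, y, window)
    starts = np.arange(len(slopes))
    ok = np.array(
        [bool(np.all(smoothed[i : i + window] >= min_level)) for i in starts]
    )
    if not ok.any():
        # grew past the detection floor but never cleanly above baseline
        flags.add("weak_signal")
        return FitnessTriple(np.nan, np.nan, efficiency, frozenset(flags))

    # pick the steepest window by a lower confidence bound on its slope, so
    # noise excursions cannot masquerade as the exponential phase
    cand = np.where(ok)[0]
    best = cand[np.argmax(slopes[cand] - 2.0 * ses[cand])]
    max_slope = float(slopes[best])
    if max_slope <= 0:
        flags.add("no_growth")
        return FitnessTriple(np.nan, np.nan, efficiency, frozenset(flags))

    rate = float(np.log(2.0) / max_slope)
    # Tangent through the steepest window, intersected with the baseline level.
    lag = float((np.log(baseline) - intercepts[best]) / max_slope)
    if lag < 0:
        lag = 0.0
        flags.add("lag_clipped")
    return FitnessTriple(lag, rate, efficiency, frozenset(flags))


class NormalizationPolicy(str, enum.Enum):
    """Order of run-averaging in the relative-trait computation.

    ``MEAN_OF_LOG_RATIOS`` (default): the log2 ratio to the run's reference
    mean is formed per run, then averaged over runs.  ``LOG_OF_MEAN_RATIO``:
    the per-run ratios are averaged first and logged once.
    """

    MEAN_OF_LOG_RATIOS = "mean_of_log_ratios"
    LOG_OF_MEAN_RATIO = "log_of_mean_ratio"


@dataclass(frozen=True)
class RelativeTrait:
    """Log2 relative fitness (positive = superior proliferation)."""

    strain_id: str
    trait_id: str
    value: float
    n_runs: int
    flags: frozenset = frozenset()


def compute_relative_trait(
    strain_values: Mapping[str, float],
    reference_values: Mapping[str, Iterable[float]],
    variable: str,
    strain_id: str = "",
    environment_id: str = "",
    policy: NormalizationPolicy = NormalizationPolicy.MEAN_OF_LOG_RATIOS,
) -> RelativeTrait:
    """Normalize per-run fitness values to run-matched reference measurements.

    For lag and rate (where smaller raw values are better) the per-run value is
    ``log2(reference_run_mean / strain_value)``; for efficiency (larger is
    better) the ratio is inverted so positive always means superior
    proliferation.  Runs are combined according to ``policy``.

    Nonpositive raw values cannot be log-transformed and yield a missing value
    flagged ``"nonpositive"``; a run without reference measurements raises.
    """
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    tid = trait_id(environment_id, variable) if environment_id else variable
    flags: set[str] = set()
    ratios = []
    for run, x in strain_values.items():
        if run not in reference_values:
            raise ValueError(f"no reference measurement for run {run!r}")
        ref = np.asarray(list(reference_values[run]), dtype=float)
        if len(ref) == 0:
            raise ValueError(f"no reference measurement for run {run!r}")
        ref_mean = float(np.mean(ref))
        if not np.isfinite(x) or x <= 0 or ref_mean <= 0:
            flags.add("nonpositive")
            continue
        if variable == "efficiency":
            ratios.append(x / ref_mean)
        else:
            ratios.append(ref_mean / x)
    if not ratios:
        return RelativeTrait(strain_id, tid, np.nan, 0, frozenset(flags))
    if policy is NormalizationPolicy.MEAN_OF_LOG_RATIOS:
        value = float(np.mean(np.log2(ratios)))
    else:
        value = float(np.log2(np.mean(ratios)))
    return RelativeTrait(strain_id, tid, value, len(ratios), frozenset(flags))


def build_trait_matrix(
    relative_traits: Iterable[RelativeTrait],
    annotations=None,
    trait_classes: Mapping[str, str] | None = None,
) -> tuple[TraitMatrix, dict]:
    """Assemble relative traits into a strains x traits matrix.

    Replicate-level entries must already be averaged (one value per
    (strain, trait)); conflicting duplicates raise with the offenders listed.
    Returns the matrix and a coverage report of missing cells.
    """
    rows = [
        (rt.strain_id, rt.trait_id, rt.value)
        for rt in relative_traits
    ]
    tidy = pd.DataFrame(rows, columns=["strain_id", "trait_id", "value"])
    dup = tidy.duplicated(subset=["strain_id", "trait_id"], keep=False)
    if dup.any():
        offenders = (
            tidy.loc[dup, ["strain_id", "trait_id"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise ValueError(f"duplicate (strain, trait) pairs: {sorted(offenders)}")
    values = tidy.pivot(index="strain_id", columns="trait_id", values="value")
    values.columns.name = None
    if annotations is not None:
        annotations.require_strains(values.index)
    matrix = TraitMatrix(values)
    if trait_classes:
        envs = matrix.traits["environment_id"]
        matrix.traits["environment_class"] = [
            trait_classes.get(e, "unclassified") for e in envs
        ]
    return matrix, matrix.coverage_report()


def replicate_cv(replicated_values: pd.DataFrame) -> dict:
    """Coefficient of variation between replicates, on the pre-log scale.

    ``replicated_values`` is tidy with columns ``strain_id``, ``trait_id``,
    ``replicate`` and ``value`` (raw-scale fitness component).  Per
    (strain, trait) cell with >= 2 replicates, CV = sample sd / mean; cells
    with a single replicate are excluded and counted.

    Returns per-trait mean CV, the global mean CV over all cells, and the
    number of excluded single-replicate cells.
    """
    required = {"strain_id", "trait_id", "replicate", "value"}
    missing = required - set(replicated_values.columns)
    if missing:
        raise ValueError(f"replicated_values missing columns: {sorted(missing)}")
    grp = replicated_values.groupby(["strain_id", "trait_id"])["value"]
    n = grp.count()
    mean = grp.mean()
    sd = grp.std(ddof=1)
    ok = (n >= 2) & (mean != 0)
    cv = (sd[ok] / mean[ok]).abs()
    per_trait = cv.groupby(level="trait_id").mean()
    return {
        "cell_cv": cv,
        "per_trait_cv": per_trait,
        "global_mean_cv": float(cv.mean()) if len(cv) else np.nan,
        "n_excluded_single_replicate": int((n < 2).sum()),
    }
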