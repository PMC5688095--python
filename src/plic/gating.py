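"""The gating cascade: population assignment, PLA positivity and
false-positive filtering.

The cascade turns per-cell feature vectors into PLA-positive calls:

1. **population gate** -- assign each cell to a marker-defined population
   (target-high / target-low / control) from marker intensities;
2. **PLA gate** -- a 2-D threshold on (bright detail intensity, max pixel) of
   the PLA channel, set at a percentile (default 99.5) of a probes-only
   background control;
3. **localization filter** -- the same 2-D gate re-applied to features on the
   adaptive-erode (interior) mask, rejecting membranal signal, plus -- for
   nuclear targets -- a max-contour-position cutoff;
4. **area filter** -- the PLA staining area must be a compact fraction of the
   cell, rejecting diffuse autofluorescence;
5. **BDS filter** -- cells whose PLA bright detail strongly overlays the
   adjacent channel (Fisher-z similarity above 1.5) are excluded as
   channel-penetrance artifacts.

The final call is the pure conjunction of the enabled gates, so the positive
set does not depend on evaluation order; the recorded order only attributes
first-failure reasons for auditing.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import UNASSIGNED, CellImage, Population
from .compensation import SpilloverMatrix, compensate_sample, estimate_spillover
from .imageops import FeatureConfig, extract_features

__all__ = [
    "PopulationGateConfig",
    "GatingConfig",
    "gate_population",
    "set_pla_threshold",
    "set_interior_threshold",
    "localization_filter",
    "bds_filter",
    "apply_gates",
    "run_pipeline",
    "PipelineResult",
    "PLAGater",
]

logger = logging.getLogger(__name__)

#: Gate evaluation order used for first-failure attribution.
DEFAULT_CASCADE = ("population", "pla", "localization", "area", "bds")


@dataclass
class PopulationGateConfig:
    """Marker-intensity rules assigning cells to populations.

    ``policy`` is ``"fixed"`` (use the given cutoffs on the per-pixel mean
    marker intensity) or ``"otsu"`` (split each marker's log-intensity
    distribution in two; only meaningful when both modes are present in the
    sample).  Cells with every marker below ``floor`` are UNASSIGNED, as are
    cells high in both the target and the control marker (doublet-like).
    """

    target_marker: str = "CD80"
    control_marker: str = "CD45"
    policy: str = "fixed"
    target_cutoff: float = 50.0
    control_cutoff: float = 50.0
    floor: float = 0.5
    stat: str = "mean"

    def __post_init__(self):
        if self.policy not in ("fixed", "otsu"):
            raise ValueError("policy must be 'fixed' or 'otsu'")


@dataclass
class GatingConfig:
    """All thresholds and the ordered filter cascade.

    ``cascade`` lists the enabled gates; the TEC-style analysis uses the full
    cascade while the macrophage-style analysis uses only
    ``("population", "pla")``.  ``nuclear_required`` adds the
    max-contour-position cutoff inside the localization filter for targets
    expressed exclusively in the nucleus.
    """

    pla_channel: str = "PLA"
    control_percentile: float = 99.5
    mcp_max: float = 0.6
    area_min_px: float = 2.0
    area_max_frac: float = 0.40
    bds_cutoff: float = 1.5
    bds_pair: Optional[tuple] = None   # default: PLA vs adjacent channel
    nuclear_required: bool = True
    bds_missing_strict: bool = False   # missing BDS fails when True
    cascade: tuple = DEFAULT_CASCADE
    population: PopulationGateConfig = field(default_factory=PopulationGateConfig)

    def __post_init__(self):
        if not 0 < self.control_percentile < 100:
            raise ValueError("control percentile must be in (0, 100)")
        if self.area_min_px < 0 or not 0 < self.area_max_frac <= 1:
            raise ValueError("invalid area range")
        if not np.isfinite(self.mcp_max):
            raise ValueError("mcp_max must be finite")
        unknown = set(self.cascade) - set(DEFAULT_CASCADE)
        if unknown:
            raise ValueError(f"unknown cascade stages: {sorted(unknown)}")
        self.cascade = tuple(self.cascade)
        if isinstance(self.population, dict):
            self.population = PopulationGateConfig(**self.population)

    @classmethod
    def bmdm(cls, **kw) -> "GatingConfig":
        """Reduced cascade: raw PLA gate only (macrophage-style analysis)."""
        kw.setdefault("cascade", ("population", "pla"))
        kw.setdefault("nuclear_required", False)
        return cls(**kw)

    def to_yaml(self, path) -> None:
        import yaml

        doc = asdict(self)
        doc["cascade"] = list(self.cascade)
        if doc.get("bds_pair") is not None:
            doc["bds_pair"] = list(doc["bds_pair"])
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GatingConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "cascade" in doc:
            doc["cascade"] = tuple(doc["cascade"])
        if doc.get("bds_pair") is not None:
            doc["bds_pair"] = tuple(doc["bds_pair"])
        return cls(**doc)


def _marker_column(features: pd.DataFrame, marker: str, stat: str) -> pd.Series:
    col = f"{marker}_{stat}"
    if col not in features.columns:
        raise KeyError(f"missing marker feature column {col!r}")
    return features[col]


def gate_population(
    features: pd.DataFrame, config: GatingConfig
) -> tuple[pd.Series, dict]:
    """Assign each cell a population label from marker intensities.

    Returns ``(labels, cutoffs_used)``; labels are the population values or
    ``UNASSIGNED``.
    """
    pop = config.population
    tgt = _marker_column(features, pop.target_marker, pop.stat).to_numpy(float)
    ctl = _marker_column(features, pop.control_marker, pop.stat).to_numpy(float)

    if pop.policy == "otsu":
        from skimage.filters import threshold_otsu

        t_cut = float(10 ** threshold_otsu(np.log10(tgt + 1.0)) - 1.0)
        c_cut = float(10 ** threshold_otsu(np.log10(ctl + 1.0)) - 1.0)
    else:
        t_cut, c_cut = float(pop.target_cutoff), float(pop.control_cutoff)

    labels = np.full(len(features), UNASSIGNED, dtype=object)
    with np.errstate(invalid="ignore"):
        dim = (tgt < pop.floor) & (ctl < pop.floor)
        is_ctl = (ctl > c_cut) & (tgt <= t_cut)
        is_hi = (tgt > t_cut) & (ctl <= c_cut)
        is_lo = (tgt <= t_cut) & (ctl <= c_cut) & ~dim
    labels[is_lo] = Population.TARGET_LO.value
    labels[is_hi] = Population.TARGET_HI.value
    labels[is_ctl] = Population.CONTROL_POP.value
    cutoffs = {"target_cutoff": t_cut, "control_cutoff": c_cut,
               "floor": pop.floor, "policy": pop.policy}
    logger.info("population gate cutoffs: %s", cutoffs)
    return pd.Series(labels, index=features.index, name="population"), cutoffs


def set_pla_threshold(
    control_features: pd.DataFrame,
    percentile: float = 99.5,
    pla_channel: str = "PLA",
) -> tuple[float, float]:
    """2-D PLA positivity threshold from a probes-only background control.

    Returns ``(bdi_cut, max_pixel_cut)``: the given percentile (NumPy linear
    interpolation rule) of the control's PLA-channel bright-detail-intensity
    and max-pixel distributions, with a machine-epsilon guard so that exact
    zeros never pass.  A cell is raw PLA-positive iff *both* features exceed
    their cutoff.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    if len(control_features) == 0:
        raise ValueError("probes-only control is empty")
    bdi = control_features[f"{pla_channel}_bdi"].to_numpy(float)
    mp = control_features[f"{pla_channel}_max_pixel"].to_numpy(float)
    if np.isnan(bdi).all() or np.isnan(mp).all():
        raise ValueError("control features are all missing")
    bdi_cut = float(np.nanpercentile(bdi, percentile))
    mp_cut = float(np.nanpercentile(mp, percentile))
    eps = float(np.finfo(float).tiny)
    thresholds = (max(bdi_cut, eps), max(mp_cut, eps))
    logger.info("PLA gate (percentile %.3g): bdi > %.6g and max_pixel > %.6g",
                percentile, *thresholds)
    return thresholds


def set_interior_threshold(
    control_features: pd.DataFrame,
    percentile: float = 99.5,
    pla_channel: str = "PLA",
) -> tuple[float, float]:
    """PLA gate recalibrated for the adaptive-erode (interior) mask.

    The same percentile rule as :func:`set_pla_threshold`, applied to the
    probes-only control's erode-mask features.  The gate is re-set on the
    mask it is evaluated on because summed features scale with mask area, so
    the morphology-mask cutoffs would be systematically too high for the
    smaller interior mask.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    if len(control_features) == 0:
        raise ValueError("probes-only control is empty")
    bdi = control_features[f"{pla_channel}_bdi_erode"].to_numpy(float)
    mp = control_features[f"{pla_channel}_max_pixel_erode"].to_numpy(float)
    if np.isnan(bdi).all() or np.isnan(mp).all():
        raise ValueError("control erode features are all missing")
    eps = float(np.finfo(float).tiny)
    thresholds = (
        max(float(np.nanpercentile(bdi, percentile)), eps),
        max(float(np.nanpercentile(mp, percentile)), eps),
    )
    logger.info("interior PLA gate: bdi_erode > %.6g and max_pixel_erode > %.6g",
                *thresholds)
    return thresholds


def _raw_pla_pos(features, thresholds, pla_channel) -> pd.Series:
    bdi_cut, mp_cut = thresholds
    return (features[f"{pla_channel}_bdi"] > bdi_cut) & (
        features[f"{pla_channel}_max_pixel"] > mp_cut
    )


def localization_filter(
    features: pd.DataFrame, config: GatingConfig, interior_thresholds: tuple
) -> pd.Series:
    """Interior-signal test: the PLA gate must still pass on the
    adaptive-erode mask (membranal signal does not), and -- when
    ``nuclear_required`` -- the max contour position must be at most
    ``mcp_max``.  Missing interior features fail the filter.

    ``interior_thresholds`` are the erode-mask cutoffs from
    :func:`set_interior_threshold`.
    """
    ch = config.pla_channel
    for col in (f"{ch}_bdi_erode", f"{ch}_max_pixel_erode"):
        if col not in features.columns:
            raise KeyError(f"missing adaptive-erode feature {col!r}")
    bdi_cut, mp_cut = interior_thresholds
    interior = (features[f"{ch}_bdi_erode"] > bdi_cut) & (
        features[f"{ch}_max_pixel_erode"] > mp_cut
    )
    if config.nuclear_required:
        interior &= features[f"{ch}_mcp"] <= config.mcp_max
    return interior.fillna(False)


def area_filter(features: pd.DataFrame, config: GatingConfig) -> pd.Series:
    """PLA staining area within ``[area_min_px, area_max_frac * mask_area]``."""
    area = features[f"{config.pla_channel}_area"]
    upper = config.area_max_frac * features["mask_area"]
    return ((area >= config.area_min_px) & (area <= upper)).fillna(False)


def bds_filter(
    features: pd.DataFrame,
    pair: tuple,
    cutoff: float = 1.5,
    missing_strict: bool = False,
) -> pd.Series:
    """Pass iff the bright-detail similarity of the pair is <= ``cutoff``.

    High BDS reflects strong bright-spot overlay between the two channels
    (bleed-through that compensation cannot remove).  Missing BDS passes with
    a flag unless ``missing_strict``.
    """
    col = f"BDS_{pair[0]}_{pair[1]}"
    if col not in features.columns:
        raise KeyError(f"missing BDS feature column {col!r}")
    bds = features[col]
    ok = bds <= cutoff
    missing = bds.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} cells have no BDS value", stacklevel=2)
    return ok.where(~missing, other=not missing_strict)


def _default_bds_pair(features: pd.DataFrame, pla_channel: str) -> Optional[tuple]:
    prefix = f"BDS_{pla_channel}_"
    for col in features.columns:
        if col.startswith(prefix):
            return (pla_channel, col[len(prefix):])
    return None


def apply_gates(
    features: pd.DataFrame,
    config: GatingConfig,
    thresholds: tuple,
    interior_thresholds: Optional[tuple] = None,
    labels: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Evaluate every enabled gate and assemble the per-cell call table.

    Returns a DataFrame with the population label, per-gate booleans, the
    final PLA-positive conjunction, the first failed gate under the cascade
    order, and the full semicolon-joined list of failure reasons.  Cells that
    fail population assignment carry no final call (``final_pla_pos`` is
    ``False`` and the population is ``UNASSIGNED``; summaries exclude them).
    """
    cascade = config.cascade
    if labels is None:
        if "population" in cascade:
            labels, _ = gate_population(features, config)
        else:
            labels = pd.Series(Population.TARGET_HI.value, index=features.index)
    assigned = labels != UNASSIGNED

    calls = pd.DataFrame(index=features.index)
    calls["population"] = labels
    calls["pla_raw_pos"] = _raw_pla_pos(features, thresholds, config.pla_channel)

    if "localization" in cascade:
        calls["localization_pass"] = localization_filter(
            features, config, interior_thresholds or thresholds
        )
    else:
        calls["localization_pass"] = True
    if "area" in cascade:
        calls["area_pass"] = area_filter(features, config)
    else:
        calls["area_pass"] = True
    if "bds" in cascade:
        pair = config.bds_pair or _default_bds_pair(features, config.pla_channel)
        if pair is None:
            raise KeyError("no BDS feature available for the bds gate")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            calls["bds_pass"] = bds_filter(
                features, pair, config.bds_cutoff, config.bds_missing_strict
            )
    else:
        calls["bds_pass"] = True

    gate_cols = {
        "population": assigned,
        "pla": calls["pla_raw_pos"],
        "localization": calls["localization_pass"],
        "area": calls["area_pass"],
        "bds": calls["bds_pass"],
    }
    final = pd.Series(True, index=features.index)
    for stage in cascade:
        final &= gate_cols[stage]
    calls["final_pla_pos"] = final

    first_fail = np.full(len(features), "", dtype=object)
    reasons = [[] for _ in range(len(features))]
    for stage in cascade:
        failed = ~gate_cols[stage].to_numpy()
        for i in np.flatnonzero(failed):
            reasons[i].append(stage)
        newly = failed & (first_fail == "")
        first_fail[newly] = stage
    calls["first_fail"] = first_fail
    calls["reasons"] = [";".join(r) for r in reasons]
    return calls


def summarize_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Percent PLA-positive per population (UNASSIGNED cells excluded)."""
    rows = []
    assigned = calls[calls["population"] != UNASSIGNED]
    for pop, grp in assigned.groupby("population", sort=True):
        n = len(grp)
        n_pos = int(grp["final_pla_pos"].sum())
        rows.append({
            "population": pop,
            "n": n,
            "n_pos": n_pos,
            "pct_pla_pos": 100.0 * n_pos / n if n else float("nan"),
        })
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    """Per-cell audit trail plus per-sample summaries."""

    calls: pd.DataFrame        # all samples, with a 'sample' column
    summary: pd.DataFrame      # sample x population percentages
    thresholds: tuple          # (bdi_cut, max_pixel_cut) actually used
    population_cutoffs: dict
    interior_thresholds: Optional[tuple] = None
    spillover: Optional[SpilloverMatrix] = None


def run_pipeline(
    samples: Mapping[str, Sequence[CellImage]],
    probes_only: Sequence[CellImage],
    config: Optional[GatingConfig] = None,
    feature_config: Optional[FeatureConfig] = None,
    spillover: Optional[SpilloverMatrix] = None,
    controls: Optional[Mapping[str, Sequence[CellImage]]] = None,
) -> PipelineResult:
    """Run the full analysis: compensation, features, population gate, PLA
    gate against the probes-only control, and the false-positive filters.

    ``samples`` maps sample names to cell lists.  When single-stain
    ``controls`` are given the spillover matrix is estimated from them;
    an explicit ``spillover`` matrix takes precedence.  The probes-only
    control is compensated with the same matrix before thresholds are set.
    """
    config = config or GatingConfig()
    feature_config = feature_config or FeatureConfig()
    if len(probes_only) == 0:
        raise ValueError("probes-only control is required and non-empty")

    if spillover is None and controls is not None:
        spillover = estimate_spillover(controls)
    if spillover is not None:
        probes_only = compensate_sample(probes_only, spillover)
        samples = {
            name: compensate_sample(cells, spillover)
            for name, cells in samples.items()
        }

    control_features = extract_features(probes_only, feature_config)
    thresholds = set_pla_threshold(
        control_features, config.control_percentile, config.pla_channel
    )
    interior = None
    if "localization" in config.cascade:
        interior = set_interior_threshold(
            control_features, config.control_percentile, config.pla_channel
        )

    all_calls = []
    pop_cutoffs: dict = {}
    for name, cells in samples.items():
        feats = extract_features(cells, feature_config)
        if "population" in config.cascade:
            labels, pop_cutoffs = gate_population(feats, config)
        else:
            labels = None
        calls = apply_gates(feats, config, thresholds, interior, labels)
        calls.insert(0, "sample", name)
        all_calls.append(calls)
    calls = pd.concat(all_calls) if all_calls else pd.DataFrame()

    summaries = []
    for name, grp in calls.groupby("sample", sort=False):
        s = summarize_calls(grp)
        s.insert(0, "sample", name)
        summaries.append(s)
    summary = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    return PipelineResult(
        calls=calls,
        summary=summary,
        thresholds=thresholds,
        population_cutoffs=pop_cutoffs,
        interior_thresholds=interior,
        spillover=spillover,
    )


class PLAGater(BaseEstimator):
    """scikit-learn style gate: fit on probes-only features, predict calls.

    ``fit`` learns the 2-D PLA threshold from a probes-only feature table;
    ``predict`` returns the final PLA-positive boolean per cell of a feature
    table, and :meth:`call` the full audit table.  The gating configuration is
    a single ``config`` parameter so the estimator clones cleanly.
    """

    def __init__(self, config: Optional[GatingConfig] = None):
        self.config = config

    def _cfg(self) -> GatingConfig:
        return self.config or GatingConfig()

    def fit(self, X: pd.DataFrame, y=None):
        cfg = self._cfg()
        self.bdi_cut_, self.max_pixel_cut_ = set_pla_threshold(
            X, cfg.control_percentile, cfg.pla_channel
        )
        if "localization" in cfg.cascade:
            self.interior_thresholds_ = set_interior_threshold(
                X, cfg.control_percentile, cfg.pla_channel
            )
        else:
            self.interior_thresholds_ = None
        return self

    @property
    def thresholds_(self) -> tuple:
        return (self.bdi_cut_, self.max_pixel_cut_)

    def call(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "bdi_cut_"):
            raise ValueError("PLAGater is not fitted")
        return apply_gates(X, self._cfg(), self.thresholds_,
                           self.interior_thresholds_)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.call(X)["final_pla_pos"].to_numpy(bool)
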