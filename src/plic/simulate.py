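"""Synthetic single-cell image generator with ground truth.

Emulates the statistical structure that the gating cascade assumes: a
marker-defined target population containing a planted fraction of cells with
nuclear-speckle PLA puncta, membranal nonspecific probe binding, diffuse
autofluorescent cells, linear channel spillover, and a probes-only background
sample.  Every draw is recorded in a ground-truth table so recovery can be
scored against the planted classes.

The generator is deliberately geometric rather than optical: one centred cell
per image, Gaussian-profile puncta, additive Gaussian read noise floored at
zero, log-normal marker intensities within a population, and spillover applied
as linear mixing of the noise-free signal.  See ``docs/methods.md`` for what
this does and does not emulate.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core import (
    ROLE_BRIGHTFIELD,
    ROLE_MARKER,
    ROLE_PLA,
    CellClass,
    CellImage,
    Population,
)

__all__ = [
    "SceneParams",
    "GroundTruth",
    "PlacementError",
    "generate_cell",
    "generate_sample",
    "generate_probes_only",
    "generate_single_stain_controls",
    "nuclear_scenario_mix",
    "knockout_scenario_mix",
    "Scenario",
]


class PlacementError(RuntimeError):
    """Raised when puncta cannot be placed inside the class compartment."""


DEFAULT_CHANNELS = ("BF", "PLA", "CD80", "CD45")
DEFAULT_ROLES = (ROLE_BRIGHTFIELD, ROLE_PLA, ROLE_MARKER, ROLE_MARKER)

#: Per-pixel marker intensity means by population (arbitrary intensity units).
#: CD80-like separates TARGET_HI from TARGET_LO; CD45-like marks CONTROL_POP.
DEFAULT_MARKER_MEANS = {
    "CD80": {
        Population.TARGET_HI: 150.0,
        Population.TARGET_LO: 12.0,
        Population.CONTROL_POP: 8.0,
    },
    "CD45": {
        Population.TARGET_HI: 5.0,
        Population.TARGET_LO: 5.0,
        Population.CONTROL_POP: 150.0,
    },
}


@dataclass
class SceneParams:
    """Geometry, intensity and noise parameters of the simulated scene.

    All intensities are in arbitrary detector units; all lengths in pixels.
    Defaults are chosen so that the planted classes reproduce the qualitative
    morphologies the gating cascade discriminates: bright compact nuclear
    puncta (rolling-circle amplification products are far brighter than
    nonspecific probe stickiness), dim membranal background puncta, and
    textured diffuse autofluorescence.
    """

    image_side: int = 49                    # odd, one centred cell per image
    cell_radius: float = 21.0
    nucleus_radius_fraction: float = 0.6    # nucleus radius / cell radius
    speckle_count_mean: float = 5.0         # Poisson mean, zero-truncated for positives
    speckle_radius: float = 1.5             # Gaussian punctum sigma = radius / 2
    speckle_amplitude: float = 400.0        # peak intensity of a true punctum
    amplitude_cv: float = 0.25              # log-normal jitter on amplitudes
    membrane_ring_width: float = 2.0        # band straddling the cell boundary
    membrane_count_mean: float = 8.0        # puncta per membranal-FP cell
    membrane_amplitude: float = 150.0
    diffuse_level: float = 60.0             # autofluorescence elevation
    diffuse_texture_cv: float = 0.35        # per-pixel Gaussian texture on it
    noise_sd: float = 2.0                   # additive read noise, floored at 0
    bf_level: float = 100.0                 # brightfield-proxy disk intensity
    marker_cv: float = 0.35                 # log-normal spread of marker means
    single_stain_level: float = 500.0       # planted level in compensation controls
    background_membrane_count_mean: float = 1.5   # probes-only background puncta
    background_membrane_amplitude: float = 40.0
    background_diffuse_level: float = 8.0
    bleed_coeff: float = 0.5                # uncompensatable bleed fraction
    channel_names: tuple = DEFAULT_CHANNELS
    roles: tuple = DEFAULT_ROLES
    marker_means: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_MARKER_MEANS.items()
    })
    spillover: Optional[np.ndarray] = None  # K x K, rows = source channel
    keep_premix: bool = False               # retain pre-mixing grids as oracle

    def __post_init__(self):
        if self.image_side < 9 or self.image_side % 2 == 0:
            raise ValueError("image_side must be odd and >= 9")
        if self.cell_radius <= 0:
            raise ValueError("cell_radius must be positive")
        if not 0 < self.nucleus_radius_fraction < 1:
            raise ValueError("nucleus_radius_fraction must be in (0, 1)")
        if self.speckle_radius <= 0 or self.membrane_ring_width <= 0:
            raise ValueError("radii and widths must be positive")
        if self.speckle_radius >= self.nucleus_radius:
            raise PlacementError(
                "speckle_radius must be smaller than the nucleus radius so "
                "nuclear puncta fit inside their compartment"
            )
        half = (self.image_side - 1) / 2
        if self.cell_radius + self.membrane_ring_width / 2 > half:
            raise ValueError("cell (plus membrane band) does not fit in the image")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spillover is not None:
            s = np.asarray(self.spillover, dtype=float)
            k = len(self.channel_names)
            if s.shape != (k, k):
                raise ValueError("spillover must be K x K for K channels")
            self.spillover = s

    @property
    def nucleus_radius(self) -> float:
        return self.cell_radius * self.nucleus_radius_fraction

    @property
    def pla_channel(self) -> str:
        return self.channel_names[self.roles.index(ROLE_PLA)]

    @property
    def brightfield_channel(self) -> str:
        return self.channel_names[self.roles.index(ROLE_BRIGHTFIELD)]


@dataclass
class GroundTruth:
    """Planted per-cell classes and parameters for a generated sample."""

    table: pd.DataFrame            # one row per cell
    n: int
    seed: Optional[int]
    mix: Optional[dict] = None
    premix: Optional[list] = None  # pre-mixing (C, h, w) grids if requested

    @property
    def planted_fraction(self) -> float:
        """Empirical fraction of NUCLEAR_PLA_POS cells."""
        if self.n == 0:
            return float("nan")
        return float(
            (self.table["cell_class"] == CellClass.NUCLEAR_PLA_POS.value).mean()
        )


def _radial_grid(side: int) -> np.ndarray:
    c = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    return np.hypot(yy - c, xx - c)


def _truncated_poisson(rng: np.random.Generator, lam: float, max_tries: int = 1000) -> int:
    """Poisson draw conditioned on being >= 1 (a planted cell has signal)."""
    for _ in range(max_tries):
        n = int(rng.poisson(lam))
        if n >= 1:
            return n
    raise PlacementError(f"could not draw a nonzero punctum count at mean {lam}")


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Log-normal draw parameterised by its median ``mean`` and log-sd ``cv``."""
    if cv <= 0:
        return mean if size is None else np.full(size, float(mean))
    return mean * np.exp(rng.normal(0.0, cv, size=size))


def _render_puncta(grid, rows, cols, amps, sigma):
    """Add Gaussian-profile puncta in place (window of +/- 4 sigma)."""
    side = grid.shape[0]
    w = int(math.ceil(4 * sigma))
    for r, c, a in zip(rows, cols, amps):
        r0, r1 = max(0, int(r) - w), min(side, int(r) + w + 1)
        c0, c1 = max(0, int(c) - w), min(side, int(c) + w + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        grid[r0:r1, c0:c1] += a * np.exp(
            -((yy - r) ** 2 + (xx - c) ** 2) / (2.0 * sigma**2)
        )


def _place_in_disk(rng, n, radius, center):
    """n uniform points in a disk of ``radius`` around ``center`` (row, col)."""
    if radius <= 0:
        raise PlacementError("compartment radius is not positive")
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    th = rng.uniform(0, 2 * np.pi, n)
    return center + r * np.sin(th), center + r * np.cos(th)


def _place_in_band(rng, n, r_inner, r_outer, center):
    """n points uniform (by area) in the annulus [r_inner, r_outer]."""
    if not 0 <= r_inner < r_outer:
        raise PlacementError("invalid membrane band radii")
    r = np.sqrt(rng.uniform(r_inner**2, r_outer**2, n))
    th = rng.uniform(0, 2 * np.pi, n)
    return center + r * np.sin(th), center + r * np.cos(th)


def generate_cell(
    cell_class: CellClass,
    params: SceneParams,
    rng: np.random.Generator,
    population: Population = Population.TARGET_HI,
    plant_background: bool = False,
    bleed: bool = False,
    costain: bool = False,
):
    """Generate one multichannel cell image plus its ground-truth record.

    Parameters
    ----------
    cell_class
        Planted PLA-signal morphology (see :class:`~plic.core.CellClass`).
    population
        Determines marker-channel intensities (e.g. TARGET_HI gets a high
        CD80-like stain, CONTROL_POP a high CD45-like stain).
    plant_background
        Add the low-level membranal/diffuse background of a probes-only
        sample on top of the class signal.
    bleed
        Copy a fraction of the PLA signal into the spectrally adjacent
        channel *after* spillover mixing -- an artifact that compensation
        cannot remove (excluded downstream by the bright-detail-similarity
        gate).
    costain
        Plant an independent set of nuclear puncta in the adjacent channel
        (a co-stain with its own speckles, uncorrelated with the PLA ones).

    Returns
    -------
    (CellImage, dict)
        The image (spillover-mixed, noise added, floored at zero) and the
        truth record.  When ``params.keep_premix`` is set the record carries
        the noise-free pre-mixing stack under ``"premix"``.
    """
    cell_class = CellClass(cell_class)
    population = Population(population)
    side = params.image_side
    center = (side - 1) / 2.0
    rr = _radial_grid(side)
    cell_mask = rr <= params.cell_radius
    k = len(params.channel_names)
    sigma = params.speckle_radius / 2.0

    premix = np.zeros((k, side, side), dtype=float)
    names = list(params.channel_names)
    i_bf = names.index(params.brightfield_channel)
    i_pla = names.index(params.pla_channel)
    premix[i_bf][cell_mask] = params.bf_level

    marker_draws = {}
    for ch, by_pop in params.marker_means.items():
        mean = by_pop[population] if population in by_pop else by_pop[population.value]
        level = float(_lognormal(rng, mean, params.marker_cv))
        premix[names.index(ch)][cell_mask] = level
        marker_draws[ch] = level

    rows = np.empty(0)
    cols = np.empty(0)
    amps = np.empty(0)
    if cell_class is CellClass.NUCLEAR_PLA_POS:
        n_spk = _truncated_poisson(rng, params.speckle_count_mean)
        reach = params.nucleus_radius - params.speckle_radius
        rows, cols = _place_in_disk(rng, n_spk, reach, center)
        amps = _lognormal(rng, params.speckle_amplitude, params.amplitude_cv, n_spk)
        _render_puncta(premix[i_pla], rows, cols, amps, sigma)
    elif cell_class is CellClass.MEMBRANAL_FP:
        n_spk = _truncated_poisson(rng, params.membrane_count_mean)
        half_w = params.membrane_ring_width / 2.0
        rows, cols = _place_in_band(
            rng, n_spk, params.cell_radius - half_w, params.cell_radius + half_w, center
        )
        amps = _lognormal(rng, params.membrane_amplitude, params.amplitude_cv, n_spk)
        _render_puncta(premix[i_pla], rows, cols, amps, sigma)
    elif cell_class is CellClass.DIFFUSE_AF:
        n_px = int(cell_mask.sum())
        texture = 1.0 + params.diffuse_texture_cv * rng.standard_normal(n_px)
        premix[i_pla][cell_mask] += np.clip(params.diffuse_level * texture, 0, None)
    # NEGATIVE: no planted PLA signal

    bg_rows = np.empty(0)
    bg_cols = np.empty(0)
    if plant_background:
        n_bg = int(rng.poisson(params.background_membrane_count_mean))
        if n_bg > 0:
            half_w = params.membrane_ring_width / 2.0
            bg_rows, bg_cols = _place_in_band(
                rng, n_bg, params.cell_radius - half_w, params.cell_radius + half_w,
                center,
            )
            bg_amps = _lognormal(
                rng, params.background_membrane_amplitude, params.amplitude_cv, n_bg
            )
            _render_puncta(premix[i_pla], bg_rows, bg_cols, bg_amps, sigma)
        premix[i_pla][cell_mask] += params.background_diffuse_level

    i_adj = i_pla + 1 if i_pla + 1 < k else i_pla - 1
    if costain:
        n_cs = _truncated_poisson(rng, params.speckle_count_mean)
        reach = params.nucleus_radius - params.speckle_radius
        cs_rows, cs_cols = _place_in_disk(rng, n_cs, reach, center)
        cs_amps = _lognormal(rng, params.speckle_amplitude, params.amplitude_cv, n_cs)
        _render_puncta(premix[i_adj], cs_rows, cs_cols, cs_amps, sigma)

    if params.spillover is not None:
        observed = np.einsum("sc,shw->chw", params.spillover, premix)
    else:
        observed = premix.copy()
    if bleed:
        observed[i_adj] += params.bleed_coeff * premix[i_pla]
    if params.noise_sd > 0:
        observed = observed + rng.normal(0.0, params.noise_sd, observed.shape)
    observed = np.clip(observed, 0.0, None)

    truth = {
        "cell_class": cell_class.value,
        "population": population.value,
        "n_speckles": int(len(rows)),
        "speckle_rows": list(np.round(rows, 4)),
        "speckle_cols": list(np.round(cols, 4)),
        "speckle_amps": list(np.round(np.atleast_1d(amps), 4)),
        "n_background_puncta": int(len(bg_rows)),
        "has_background": bool(plant_background),
        "bleed": bool(bleed),
        "costain": bool(costain),
        **{f"marker_{ch}": lvl for ch, lvl in marker_draws.items()},
    }
    if params.keep_premix:
        truth["premix"] = premix
    image = CellImage(observed, params.channel_names, params.roles)
    return image, truth


def _normalise_mix(mix: Mapping) -> list:
    entries = []
    total = 0.0
    for (pop, cls), frac in mix.items():
        frac = float(frac)
        if frac < 0:
            raise ValueError("mix fractions must be >= 0")
        entries.append((Population(pop), CellClass(cls), frac))
        total += frac
    if not entries or abs(total - 1.0) > 1e-8:
        raise ValueError(f"mix fractions must sum to 1 (got {total})")
    return entries


def generate_sample(
    n: int,
    mix: Mapping,
    params: SceneParams,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    plant_background: bool = True,
    bleed_fraction: float = 0.0,
):
    """Generate ``n`` cells with classes/populations drawn i.i.d. from ``mix``.

    ``mix`` maps ``(population, cell_class)`` pairs to fractions summing to 1.
    Each cell's class is an independent draw, so the empirical count of any
    class is Binomial(n, fraction).  With ``plant_background`` (the default)
    every cell additionally carries the same low-level nonspecific probe
    background that the probes-only threshold-setting control exhibits, since
    probe stickiness affects all samples of an experiment alike.

    Returns ``(cells, GroundTruth)``; reproducible bit-for-bit given ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    entries = _normalise_mix(mix)
    if rng is None:
        rng = np.random.default_rng(seed)
    if n == 0:
        warnings.warn("generating an empty sample (n=0)", stacklevel=2)
        table = pd.DataFrame(columns=["cell_class", "population"])
        return [], GroundTruth(table=table, n=0, seed=seed, mix=dict(mix))

    probs = np.array([e[2] for e in entries])
    idx = rng.choice(len(entries), size=n, p=probs)
    bleed_flags = (
        rng.uniform(size=n) < bleed_fraction if bleed_fraction > 0 else np.zeros(n, bool)
    )

    cells = []
    records = []
    premixes = [] if params.keep_premix else None
    for i in range(n):
        pop, cls, _ = entries[idx[i]]
        img, rec = generate_cell(
            cls, params, rng, population=pop, plant_background=plant_background,
            bleed=bool(bleed_flags[i]),
        )
        if premixes is not None:
            premixes.append(rec.pop("premix"))
        rec["cell_id"] = i
        cells.append(img)
        records.append(rec)
    table = pd.DataFrame.from_records(records).set_index("cell_id")
    return cells, GroundTruth(table=table, n=n, seed=seed, mix=dict(mix),
                              premix=premixes)


def generate_probes_only(
    n: int,
    params: SceneParams,
    seed: Optional[int] = None,
    population_mix: Optional[Mapping] = None,
):
    """Probes-only background control: NEGATIVE cells with low-level
    membranal/diffuse probe background and no nuclear speckles.

    This sample mimics the assay control run without the primary antibody and
    is what the PLA positivity gate is calibrated against.
    """
    if population_mix is None:
        population_mix = {Population.TARGET_HI: 0.5, Population.CONTROL_POP: 0.5}
    mix = {
        (Population(pop), CellClass.NEGATIVE): frac
        for pop, frac in population_mix.items()
    }
    rng = np.random.default_rng(seed)
    if n == 0:
        return generate_sample(0, mix, params, seed=seed)
    entries = _normalise_mix(mix)
    probs = np.array([e[2] for e in entries])
    idx = rng.choice(len(entries), size=n, p=probs)
    cells, records = [], []
    premixes = [] if params.keep_premix else None
    for i in range(n):
        pop, cls, _ = entries[idx[i]]
        img, rec = generate_cell(cls, params, rng, population=pop,
                                 plant_background=True)
        if premixes is not None:
            premixes.append(rec.pop("premix"))
        rec["cell_id"] = i
        cells.append(img)
        records.append(rec)
    table = pd.DataFrame.from_records(records).set_index("cell_id")
    return cells, GroundTruth(table=table, n=n, seed=seed, mix=dict(mix),
                              premix=premixes)


def generate_single_stain_controls(
    spillover: np.ndarray,
    n_per_channel: int,
    params: SceneParams,
    seed: Optional[int] = None,
):
    """One control sample per channel, signal planted only in that channel.

    Each control cell is a uniform disk of (log-normally jittered) intensity
    in exactly one source channel; the spillover matrix is then applied and
    read noise added, exactly as for regular cells.  These controls are the
    input to spillover estimation.

    Returns a dict mapping channel name to a list of :class:`CellImage`.
    """
    spillover = np.asarray(spillover, dtype=float)
    k = len(params.channel_names)
    if spillover.shape != (k, k):
        raise ValueError("spillover must be K x K for K channels")
    rng = np.random.default_rng(seed)
    side = params.image_side
    rr = _radial_grid(side)
    cell_mask = rr <= params.cell_radius

    controls = {}
    for src, name in enumerate(params.channel_names):
        cells = []
        for _ in range(n_per_channel):
            premix = np.zeros((k, side, side))
            level = float(_lognormal(rng, params.single_stain_level, params.marker_cv))
            premix[src][cell_mask] = level
            observed = np.einsum("sc,shw->chw", spillover, premix)
            if params.noise_sd > 0:
                observed = observed + rng.normal(0.0, params.noise_sd, observed.shape)
            cells.append(
                CellImage(np.clip(observed, 0.0, None),
                          params.channel_names, params.roles)
            )
        controls[name] = cells
    return controls


# ---------------------------------------------------------------------------
# Scenario presets

def nuclear_scenario_mix(f: float) -> dict:
    """Target population with a planted fraction ``f`` of true positives."""
    if not 0 <= f <= 1:
        raise ValueError("planted fraction must be in [0, 1]")
    return {
        (Population.TARGET_HI, CellClass.NUCLEAR_PLA_POS): f,
        (Population.TARGET_HI, CellClass.NEGATIVE): 1.0 - f,
    }


def knockout_scenario_mix(membranal: float = 0.25, diffuse: float = 0.15) -> dict:
    """Knockout-like sample: only false-positive morphologies, no true signal."""
    if membranal + diffuse > 1:
        raise ValueError("class fractions exceed 1")
    return {
        (Population.TARGET_HI, CellClass.MEMBRANAL_FP): membranal,
        (Population.TARGET_HI, CellClass.DIFFUSE_AF): diffuse,
        (Population.TARGET_HI, CellClass.NEGATIVE): 1.0 - membranal - diffuse,
    }


@dataclass
class Scenario:
    """A declarative simulation scenario (loadable from YAML)."""

    n: int
    mix: dict
    params: SceneParams = field(default_factory=SceneParams)
    plant_background: bool = True
    bleed_fraction: float = 0.0
    name: str = "scenario"

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        mix = {}
        for entry in doc["mix"]:
            key = (Population(entry["population"]), CellClass(entry["cell_class"]))
            mix[key] = float(entry["fraction"])
        pkw = dict(doc.get("params") or {})
        if "spillover" in pkw and pkw["spillover"] is not None:
            pkw["spillover"] = np.asarray(pkw["spillover"], dtype=float)
        if "channel_names" in pkw:
            pkw["channel_names"] = tuple(pkw["channel_names"])
        if "roles" in pkw:
            pkw["roles"] = tuple(pkw["roles"])
        return cls(
            n=int(doc["n"]),
            mix=mix,
            params=SceneParams(**pkw),
            plant_background=bool(doc.get("plant_background", True)),
            bleed_fraction=float(doc.get("bleed_fraction", 0.0)),
            name=str(doc.get("name", "scenario")),
        )

    def generate(self, seed: Optional[int] = None):
        return generate_sample(
            self.n,
            self.mix,
            self.params,
            seed=seed,
            plant_background=self.plant_background,
            bleed_fraction=self.bleed_fraction,
        )
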