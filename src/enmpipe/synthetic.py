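"""Virtual-species fixtures: correlated environments with known truth.

Real inputs for this kind of analysis (bioclimatic layers, soil grids,
future climate projections, field records) are large downloads; instead a
virtual species supplies every pipeline stage with data whose ground truth
is known exactly.

The generator draws a few smooth latent factor surfaces (low-order spatial
gradients plus smoothed noise, standardised to unit variance).  Observed
"climate" variables are linear mixtures of the climate latent factors plus
independent noise — giving the strong inter-variable correlation of real
bioclim sets — and "edaphic/topographic" variables mix their own latent
factors.  True suitability is a logistic function of the *climate latent
factors* (not the observed variables), so the PCA step genuinely has a
signal subspace to recover.

Future scenarios shift the observed climate layers.  A shift expressed as
a latent-factor delta translates exactly into per-variable additive
shifts (through the mixing matrix), so the future true suitability — and
hence the true suitable-area loss the pipeline should recover — is known
in closed form.  Edaphic layers never change across scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .consensus import BinaryMap, suitable_area_km2
from .env_layers import EnvStack
from .grids import GridSpec
from .occurrences import OccurrenceSet
from .utils import rng_from

#: Canonical edaphic/topographic layer names (soil physical properties,
#: elevation and derived terrain), used in order as n_edaphic grows.
EDAPHIC_NAMES = [
    "depth_bedrock",
    "bulk_density",
    "clay",
    "coarse_fragments",
    "sand",
    "silt",
    "elevation",
    "slope",
    "aspect",
    "organic_carbon",
]


@dataclass(frozen=True)
class VirtualSpeciesSpec:
    """A species whose suitability is logistic in the climate latent factors.

    ``suitability = expit(intercept + weights . latents)``; together with
    the generator seed this fully determines every downstream truth.
    """

    weights: tuple[float, ...]
    intercept: float = 0.0


@dataclass(frozen=True)
class ScenarioShift:
    """Additive per-variable shifts, in sd units of the current layer.

    Only climate variables may appear; edaphic/topographic layers are
    constant across scenarios.
    """

    shifts_sd: tuple[tuple[str, float], ...]
    label: str = "future"

    def as_dict(self) -> dict[str, float]:
        return dict(self.shifts_sd)


@dataclass
class SyntheticScene:
    """A generated environment plus everything needed to compute truth."""

    stack: EnvStack
    climate_names: list[str]
    edaphic_names: list[str]
    climate_latents: np.ndarray  # (latent_dim, n_rows, n_cols), unit sd
    mixing_climate: np.ndarray  # (n_climate, latent_dim)
    seed: int

    @property
    def grid(self) -> GridSpec:
        return self.stack.grid

    @property
    def latent_dim(self) -> int:
        return self.climate_latents.shape[0]


def _latent_surface(rng: np.random.Generator, n_rows: int, n_cols: int) -> np.ndarray:
    """One smooth standardised latent surface: gradient + smoothed noise."""
    y, x = np.meshgrid(
        np.linspace(-1.0, 1.0, n_rows), np.linspace(-1.0, 1.0, n_cols), indexing="ij"
    )
    c = rng.normal(size=6)
    trend = c[0] * x + c[1] * y + c[2] * x * y + c[3] * x**2 + c[4] * y**2
    rough = gaussian_filter(rng.normal(size=(n_rows, n_cols)), sigma=max(2, min(n_rows, n_cols) // 10))
    rough = rough / max(rough.std(), 1e-12)
    surf = trend + 0.5 * rough
    return (surf - surf.mean()) / max(surf.std(), 1e-12)


def generate_env(
    n_rows: int = 100,
    n_cols: int = 100,
    n_climate: int = 19,
    n_edaphic: int = 10,
    latent_dim: int = 4,
    noise_sd: float = 0.3,
    seed: int = 0,
    cell_deg: float = 1.0 / 12.0,
    west: float = -63.0,
    north: float = -8.0,
) -> SyntheticScene:
    """Generate a current-scenario environmental stack with known latents.

    Defaults emulate the shape of the real inputs: 19 correlated climate
    surfaces and 10 edaphic/topographic surfaces on a 5-arc-minute grid
    over a southwestern-Amazon-like extent, mixed from ``latent_dim``
    latent factors with independent noise of sd ``noise_sd``.
    """
    if latent_dim < 2:
        raise ValueError("latent_dim must be >= 2")
    if n_rows < 10 or n_cols < 10:
        raise ValueError("grid must be at least 10 x 10")
    rng = np.random.default_rng(seed)
    grid = GridSpec(west=west, north=north, cell_deg=cell_deg, n_rows=n_rows, n_cols=n_cols)

    clim_latents = np.stack([_latent_surface(rng, n_rows, n_cols) for _ in range(latent_dim)])
    # edaphic/topographic drivers are independent of the climate drivers:
    # project the climate latents (and the mean) out of each edaphic surface
    # so static nuisance fields cannot absorb the climate signal by chance
    basis = np.column_stack(
        [np.ones(n_rows * n_cols)] + [s.ravel() for s in clim_latents]
    )
    q, _ = np.linalg.qr(basis)
    eda_latents = []
    for _ in range(2):
        s = _latent_surface(rng, n_rows, n_cols).ravel()
        s = s - q @ (q.T @ s)
        s = (s - s.mean()) / max(s.std(), 1e-12)
        eda_latents.append(s.reshape(n_rows, n_cols))
    eda_latents = np.stack(eda_latents)

    M_clim = rng.normal(size=(n_climate, latent_dim))
    M_eda = rng.normal(size=(n_edaphic, 2))

    clim = np.tensordot(M_clim, clim_latents, axes=(1, 0))
    eda = np.tensordot(M_eda, eda_latents, axes=(1, 0))
    if noise_sd > 0:
        clim = clim + noise_sd * rng.normal(size=clim.shape)
        eda = eda + noise_sd * rng.normal(size=eda.shape)

    climate_names = [f"bio{i + 1:02d}" for i in range(n_climate)]
    edaphic_names = [
        EDAPHIC_NAMES[i] if i < len(EDAPHIC_NAMES) else f"edaphic_{i + 1:02d}"
        for i in range(n_edaphic)
    ]
    stack = EnvStack(
        grid=grid,
        layer_names=climate_names + edaphic_names,
        values=np.concatenate([clim, eda]),
        scenario_label="current",
    )
    return SyntheticScene(
        stack=stack,
        climate_names=climate_names,
        edaphic_names=edaphic_names,
        climate_latents=clim_latents,
        mixing_climate=M_clim,
        seed=seed,
    )


def strong_species(
    scene: SyntheticScene, magnitude: float = 8.0, intercept: float = -12.0
) -> VirtualSpeciesSpec:
    """A rare, strongly climate-determined virtual species.

    Equal weights of ``magnitude`` on every climate latent factor give a
    steep (near-threshold) response — the odds ratio across one latent
    standard deviation is e^magnitude — and the negative intercept confines
    the suitable region to roughly the top fifth of the landscape, the
    regime of a narrowly distributed species where presence records carry
    strong signal.  Used as the default fixture for recovery and power
    studies.
    """
    return VirtualSpeciesSpec(
        weights=tuple(np.full(scene.latent_dim, magnitude)), intercept=intercept
    )


def null_species(scene: SyntheticScene) -> VirtualSpeciesSpec:
    """A species with no environmental signal: suitability 0.5 everywhere.

    Presence sampling under this species is spatially uniform, which makes
    it the null fixture for type-I-error studies of the jackknife test.
    """
    return VirtualSpeciesSpec(weights=tuple(np.zeros(scene.latent_dim)), intercept=0.0)


def true_suitability(
    spec: VirtualSpeciesSpec,
    scene: SyntheticScene,
    latent_shift: np.ndarray | None = None,
) -> np.ndarray:
    """Ground-truth suitability surface in (0, 1), optionally under a shift."""
    w = np.asarray(spec.weights, dtype=float)
    if w.size != scene.latent_dim:
        raise ValueError(f"expected {scene.latent_dim} weights, got {w.size}")
    lat = scene.climate_latents
    if latent_shift is not None:
        lat = lat + np.asarray(latent_shift, dtype=float)[:, None, None]
    eta = spec.intercept + np.tensordot(w, lat, axes=(0, 0))
    return expit(eta)


def apply_shift(stack: EnvStack, shift: ScenarioShift) -> EnvStack:
    """Shift named climate layers additively, in sd units of each layer.

    All other layers (the edaphic/topographic block) are bit-identical in
    the returned stack; the grid is unchanged.
    """
    shifts = shift.as_dict()
    unknown = [n for n in shifts if n not in stack.layer_names]
    if unknown:
        raise ValueError(f"shift names not in stack: {unknown}")
    values = stack.values.copy()
    mask = stack.mask
    for name, delta_sd in shifts.items():
        i = stack.layer_names.index(name)
        sd = float(np.std(values[i][mask]))
        values[i] = values[i] + delta_sd * sd
    return EnvStack(
        grid=stack.grid,
        layer_names=list(stack.layer_names),
        values=values,
        scenario_label=shift.label,
    )


def shift_for_latent_delta(
    scene: SyntheticScene, latent_delta: np.ndarray, label: str = "future"
) -> ScenarioShift:
    """Per-variable shift exactly equivalent to a latent-factor delta.

    A delta on the latent factors moves observed climate layer j by
    ``M_j . delta`` in absolute units; dividing by the layer's empirical sd
    expresses it in the sd units that :func:`apply_shift` consumes, so
    applying the returned shift reproduces the shifted-latent world exactly
    (same noise realisation).
    """
    delta = np.asarray(latent_delta, dtype=float)
    if delta.size != scene.latent_dim:
        raise ValueError(f"expected {scene.latent_dim} deltas, got {delta.size}")
    mask = scene.stack.mask
    shifts = []
    for j, name in enumerate(scene.climate_names):
        abs_shift = float(scene.mixing_climate[j] @ delta)
        sd = float(np.std(scene.stack.layer(name)[mask]))
        shifts.append((name, abs_shift / sd))
    return ScenarioShift(shifts_sd=tuple(shifts), label=label)


def sample_presences(
    spec: VirtualSpeciesSpec,
    scene: SyntheticScene,
    n: int,
    seed: int,
    jitter: float = 0.0,
) -> OccurrenceSet:
    """Draw n presence cells with probability proportional to suitability.

    Cells are drawn without replacement; each yields one record at the cell
    centre, optionally jittered uniformly within the cell (``jitter`` is
    the fraction of a half-cell to perturb by).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    suit = true_suitability(spec, scene)
    mask = scene.stack.mask
    probs = np.where(mask, suit, 0.0).ravel()
    positive = int((probs > 0).sum())
    if n > positive:
        raise ValueError(f"requested {n} presences but only {positive} cells have suitability > 0")
    rng = np.random.default_rng(seed)
    idx = rng.choice(probs.size, size=n, replace=False, p=probs / probs.sum())
    rows, cols = np.unravel_index(idx, scene.grid.shape)
    lons, lats = scene.grid.cell_centers(np.column_stack([rows, cols]))
    if jitter > 0:
        half = 0.5 * scene.grid.cell_deg * jitter
        lons = lons + rng.uniform(-half, half, size=n)
        lats = lats + rng.uniform(-half, half, size=n)
    table = pd.DataFrame(
        {"longitude": lons, "latitude": lats, "source": "synthetic"}
    )
    return OccurrenceSet(table=table)


def true_suitable_area(
    spec: VirtualSpeciesSpec,
    scene: SyntheticScene,
    cutoff: float,
    latent_shift: np.ndarray | None = None,
) -> float:
    """km2 of cells whose TRUE suitability >= cutoff (the recovery target)."""
    suit = true_suitability(spec, scene, latent_shift)
    vals = np.where(scene.stack.mask, (suit >= cutoff).astype(float), np.nan)
    bmap = BinaryMap(grid=scene.grid, values=vals, threshold=cutoff, scenario_label="truth")
    return suitable_area_km2(bmap)


def calibrate_latent_delta(
    scene: SyntheticScene,
    spec: VirtualSpeciesSpec,
    cutoff: float,
    target_loss_fraction: float,
    s_max: float = 20.0,
    tol: float = 1e-3,
) -> np.ndarray:
    """Latent delta (against the weight direction) producing a target loss.

    Bisects the magnitude s of ``delta = -s * w / |w|`` until the true
    suitable area falls by the requested fraction of the current true
    suitable area.  Used to construct scenarios whose true loss is a known
    study condition.
    """
    w = np.asarray(spec.weights, dtype=float)
    unit = w / np.linalg.norm(w)
    a0 = true_suitable_area(spec, scene, cutoff)
    if a0 == 0.0:
        raise ValueError("species has no true suitable area at this cutoff")

    def loss(s: float) -> float:
        a = true_suitable_area(spec, scene, cutoff, latent_shift=-s * unit)
        return 1.0 - a / a0

    lo, hi = 0.0, s_max
    if loss(hi) < target_loss_fraction:
        raise ValueError("s_max too small to reach the target loss")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if loss(mid) < target_loss_fraction:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return -0.5 * (lo + hi) * unit
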