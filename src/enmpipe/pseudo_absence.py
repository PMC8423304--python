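"""Disk-constrained pseudo-absence sampling.

With presence-only data, model calibration needs background cells treated
as absences.  The disk strategy restricts eligibility to cells whose
great-circle distance to the *nearest* presence cell centre lies within a
[d_min, d_max] band; by default the band is the minimum and maximum over
all presence-pair distances, so pseudo-absences are neither on top of
presences nor implausibly far from the sampled region.

Pseudo-absence counts follow the algorithm family: classification-tree
methods (GBM, CTA, RF) use as many pseudo-absences as presences, while the
regression-type methods (GLM, GAM, ANN, FDA, MARS, MAXENT) use 10 000 —
capped at the number of eligible cells on small grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridSpec, haversine_km, pairwise_haversine_km
from .utils import logger

#: Pseudo-absence count class per learner family.
FAMILY_PA_CLASS: dict[str, str] = {
    "GBM": "matched",
    "CTA": "matched",
    "RF": "matched",
    "GLM": "large",
    "GAM": "large",
    "ANN": "large",
    "FDA": "large",
    "MARS": "large",
    "MAXENT": "large",
}

#: Pseudo-absence count for the "large" class.
LARGE_PA_COUNT = 10_000


@dataclass(frozen=True)
class PASample:
    """A reproducible draw of pseudo-absence cells inside the disk band."""

    cell_ids: tuple[tuple[int, int], ...]
    n_requested: int
    d_min_km: float
    d_max_km: float
    seed: int
    strategy: str = "disk"


def pa_sample_to_dataframe(pa: "PASample", grid: GridSpec):
    """Tabulate a pseudo-absence sample as row/col plus lon/lat centres."""
    import pandas as pd

    cells = list(pa.cell_ids)
    lons, lats = grid.cell_centers(cells)
    return pd.DataFrame(
        {
            "row": [r for r, _ in cells],
            "col": [c for _, c in cells],
            "longitude": lons,
            "latitude": lats,
        }
    )


def presence_distance_bounds(
    presence_cells, grid: GridSpec
) -> tuple[float, float]:
    """Min and max great-circle distance over all presence cell-centre pairs."""
    cells = list(presence_cells)
    if len(cells) < 2:
        raise ValueError("need at least 2 presence cells to define distance bounds")
    lons, lats = grid.cell_centers(cells)
    d = pairwise_haversine_km(lons, lats)
    off = d[~np.eye(len(cells), dtype=bool)]
    return float(off.min()), float(off.max())


def nearest_presence_distance_km(
    grid: GridSpec, presence_cells
) -> np.ndarray:
    """Per-cell distance (km) to the nearest presence cell centre."""
    plons, plats = grid.cell_centers(list(presence_cells))
    lats = grid.lat_centers()
    lons = grid.lon_centers()
    glon, glat = np.meshgrid(lons, lats)
    d = haversine_km(
        glon.ravel()[:, None], glat.ravel()[:, None], plons[None, :], plats[None, :]
    )
    return d.min(axis=1).reshape(grid.shape)


def eligible_disk_cells(
    grid: GridSpec,
    mask: np.ndarray,
    presence_cells,
    d_min_km: float,
    d_max_km: float,
    exclude_cells=(),
) -> np.ndarray:
    """Boolean grid of cells eligible as pseudo-absences.

    Eligible = valid cell, not a presence cell, not in ``exclude_cells``
    (e.g. a left-out jackknife cell), and nearest-presence distance within
    ``[d_min_km, d_max_km]``.
    """
    dist = nearest_presence_distance_km(grid, presence_cells)
    ok = mask & (dist >= d_min_km) & (dist <= d_max_km)
    for r, c in list(presence_cells) + list(exclude_cells):
        ok[r, c] = False
    return ok


def sample_disk_pas(
    grid: GridSpec,
    mask: np.ndarray,
    presence_cells,
    n: int,
    bounds: tuple[float, float],
    seed: int,
    exclude_cells=(),
) -> PASample:
    """Draw ``n`` pseudo-absence cells uniformly without replacement.

    The candidate set is computed by :func:`eligible_disk_cells`; an error
    reports the eligible count when it cannot satisfy ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    d_min, d_max = bounds
    ok = eligible_disk_cells(grid, mask, presence_cells, d_min, d_max, exclude_cells)
    rows, cols = np.nonzero(ok)
    n_eligible = rows.size
    if n_eligible == 0:
        raise ValueError("no eligible pseudo-absence cells inside the distance band")
    if n > n_eligible:
        raise ValueError(
            f"requested {n} pseudo-absences but only {n_eligible} eligible cells"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_eligible, size=n, replace=False)
    cells = tuple((int(rows[i]), int(cols[i])) for i in idx)
    return PASample(
        cell_ids=cells, n_requested=n, d_min_km=d_min, d_max_km=d_max, seed=seed
    )


def pa_count_for_family(
    family: str, n_presences: int, n_eligible: int | None = None
) -> int:
    """Pseudo-absence count for a learner family.

    GBM/CTA/RF match the presence count; the other families use
    :data:`LARGE_PA_COUNT`, capped at the eligible-cell count (with a logged
    warning) when ``n_eligible`` is given.
    """
    try:
        cls = FAMILY_PA_CLASS[family]
    except KeyError:
        raise ValueError(f"unknown learner family {family!r}") from None
    n = n_presences if cls == "matched" else LARGE_PA_COUNT
    if n_eligible is not None and n > n_eligible:
        logger.warning(
            "capping %s pseudo-absence count %d at %d eligible cells",
            family,
            n,
            n_eligible,
        )
        n = n_eligible
    return n


def build_pa_sets(
    grid: GridSpec,
    mask: np.ndarray,
    presence_cells,
    families,
    n_sets: int,
    bounds: tuple[float, float],
    seed_base: int,
    exclude_cells=(),
) -> list[dict[str, PASample]]:
    """Draw ``n_sets`` pseudo-absence sets for the given families.

    Families of the same count class share one draw per set (one
    presence-matched sample, one large sample), mirroring a design where
    each pseudo-absence set is drawn once and reused across algorithms of
    the same configuration.
    """
    classes = sorted({FAMILY_PA_CLASS.get(f) for f in families} - {None})
    unknown = [f for f in families if f not in FAMILY_PA_CLASS]
    if unknown:
        raise ValueError(f"unknown learner families: {unknown}")
    n_pres = len(list(presence_cells))
    d_min, d_max = bounds
    ok = eligible_disk_cells(grid, mask, presence_cells, d_min, d_max, exclude_cells)
    n_eligible = int(ok.sum())
    if n_eligible == 0:
        # spread-out presences can leave the [d_min, d_max] annulus empty on
        # small grids; drop the lower bound so calibration remains possible
        logger.warning(
            "empty disk annulus [%.1f, %.1f] km; relaxing the lower bound to 0",
            d_min,
            d_max,
        )
        d_min = 0.0
        bounds = (d_min, d_max)
        ok = eligible_disk_cells(grid, mask, presence_cells, d_min, d_max, exclude_cells)
        n_eligible = int(ok.sum())
    sets: list[dict[str, PASample]] = []
    for s in range(n_sets):
        per_class: dict[str, PASample] = {}
        for ci, cls in enumerate(classes):
            fam = "GBM" if cls == "matched" else "GLM"  # representative of class
            n = pa_count_for_family(fam, n_pres, n_eligible)
            per_class[cls] = sample_disk_pas(
                grid,
                mask,
                presence_cells,
                n,
                bounds,
                seed=np.random.SeedSequence([seed_base, s, ci]).generate_state(1)[0]
                % (2**31),
                exclude_cells=exclude_cells,
            )
        sets.append(per_class)
    return sets
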