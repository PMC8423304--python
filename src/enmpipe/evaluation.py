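"""Small-sample jackknife validation with an exact binomial-type test.

With fewer than ~25 spatially unique occurrence cells, ordinary data splits
are uninformative, so validation is leave-one-out: each presence cell is
removed in turn, the full ensemble is re-calibrated on the remaining cells,
the continuous surface is cut at the MaxSensSpec threshold, and the
replicate "succeeds" if the left-out cell falls in the predicted-present
region.

Under the null hypothesis that the model is no better than random, the
probability that replicate i succeeds is p_i, the area-weighted proportion
of the valid region its binary map predicts present.  The total success
count D is then a sum of independent, *heterogeneous* Bernoulli trials, so
the exact significance is the upper tail of the Poisson-binomial
distribution, P(X >= D), computed by dynamic-programming convolution.
A homogeneous-binomial variant (using the mean of the p_i) is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import BinaryMap, binarize
from .ensemble import EnvStack, SuitabilityMap, calibrate_replicate
from .occurrences import OccurrenceSet
from .pseudo_absence import build_pa_sets, presence_distance_bounds
from .utils import derive_seed, logger


# ---------------------------------------------------------------------------
# MaxSensSpec threshold
# ---------------------------------------------------------------------------

def maxsensspec_threshold(
    presence_scores: Sequence[float], absence_scores: Sequence[float]
) -> tuple[float, float, float]:
    """Threshold maximising sensitivity + specificity.

    ``sensitivity(t)`` is the fraction of presence scores >= t and
    ``specificity(t)`` the fraction of absence scores < t.  Because both
    are step functions that only change at observed scores, the exact
    maximiser is found by scanning the midpoints of adjacent distinct
    pooled scores plus the extremes 0 and 1; ties break toward the
    smallest maximising threshold.
    """
    pres = np.asarray(presence_scores, dtype=float)
    absent = np.asarray(absence_scores, dtype=float)
    if pres.size == 0 or absent.size == 0:
        raise ValueError("presence and absence score lists must be non-empty")
    pooled = np.unique(np.concatenate([pres, absent]))
    if pooled.min() < 0.0 or pooled.max() > 1.0:
        raise ValueError("scores must lie in [0, 1]")
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    cands = np.unique(np.concatenate([[0.0], mids, [1.0]]))
    sens = (pres[None, :] >= cands[:, None]).mean(axis=1)
    spec = (absent[None, :] < cands[:, None]).mean(axis=1)
    total = sens + spec
    i = int(np.argmax(total))  # first (= smallest) maximiser: cands is sorted
    return float(cands[i]), float(sens[i]), float(spec[i])


# ---------------------------------------------------------------------------
# Area-weighted predicted-presence proportion
# ---------------------------------------------------------------------------

def area_weighted_presence_proportion(bmap: BinaryMap) -> float:
    """Fraction of valid *area* (not cell count) predicted present.

    Cell areas come from the spherical-band closed form, so high-latitude
    cells weigh less.  This proportion parameterises the null model of the
    jackknife test: a random point has this probability of landing in the
    predicted-present region.
    """
    areas = bmap.grid.row_cell_area_km2()[:, None]
    valid = bmap.mask
    total = float(np.sum(areas * valid))
    if total == 0.0:
        raise ValueError("binary map has no valid cells")
    present = float(np.sum(areas * bmap.present))
    return present / total


# ---------------------------------------------------------------------------
# Exact Poisson-binomial tail
# ---------------------------------------------------------------------------

def poisson_binomial_pmf(p_list: Sequence[float]) -> np.ndarray:
    """PMF of a sum of independent Bernoulli(p_i), by DP convolution."""
    p = np.asarray(p_list, dtype=float)
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("success probabilities must lie in [0, 1]")
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for pi in p:
        pmf[1:] = pmf[1:] * (1.0 - pi) + pmf[:-1] * pi
        pmf[0] *= 1.0 - pi
    return pmf


def poisson_binomial_pvalue(p_list: Sequence[float], D: int) -> float:
    """Exact upper tail P(X >= D) for X = sum of Bernoulli(p_i)."""
    n = len(p_list)
    if not 0 <= D <= n:
        raise ValueError(f"D={D} outside [0, {n}]")
    if D == 0:
        return 1.0
    pmf = poisson_binomial_pmf(p_list)
    return float(np.clip(pmf[D:].sum(), 0.0, 1.0))


def homogeneous_binomial_pvalue(p_list: Sequence[float], D: int) -> float:
    """Binomial tail P(X >= D) at the mean success probability."""
    n = len(p_list)
    if not 0 <= D <= n:
        raise ValueError(f"D={D} outside [0, {n}]")
    if D == 0:
        return 1.0
    p_bar = float(np.mean(p_list))
    return float(np.clip(stats.binom.sf(D - 1, n, p_bar), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Jackknife
# ---------------------------------------------------------------------------

@dataclass
class JackknifeReport:
    """Per-replicate jackknife outcomes and the overall exact test."""

    rows: pd.DataFrame  # one row per left-out cell
    n: int
    D: int
    p_value: float
    binomial_mode: str = "poisson_binomial"

    @property
    def mean_threshold(self) -> float:
        return float(self.rows["threshold"].mean())

    def summary(self) -> dict:
        return {
            "n": self.n,
            "D": self.D,
            "p_value": self.p_value,
            "mean_threshold": self.mean_threshold,
            "binomial_mode": self.binomial_mode,
        }

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


@dataclass
class JackknifeResult:
    """A report plus the per-replicate binary maps needed for consensus."""

    report: JackknifeReport
    binary_maps: dict[str, list[BinaryMap]]  # scenario -> one map per replicate
    success_flags: list[int]


#: Signature for an injectable calibrator: (training_cells, pa_sets,
#: score_stacks, seed) -> {scenario: SuitabilityMap}.  The default wraps
#: :func:`enmpipe.ensemble.calibrate_replicate`; tests inject fixed "oracle"
#: surfaces through the same seam.
Calibrator = Callable[[list, list, Mapping[str, EnvStack], int], Mapping[str, SuitabilityMap]]


def jackknife_run(
    occ: OccurrenceSet,
    score_stacks: Mapping[str, EnvStack],
    *,
    families: Sequence[str],
    n_pa_sets: int = 10,
    n_runs: int = 10,
    seed: int = 0,
    train_scenario: str = "current",
    bounds: tuple[float, float] | None = None,
    binomial: str = "poisson_binomial",
    hyperparams: Mapping[str, dict] | None = None,
    calibrator: Calibrator | None = None,
) -> JackknifeResult:
    """Leave-one-out validation of the full ensemble pipeline.

    For each left-out presence cell: re-draw pseudo-absence sets from the
    remaining cells (the left-out cell is excluded from eligibility — no
    leakage), re-calibrate the ensemble, take the MaxSensSpec threshold of
    training-presence scores against the distinct pooled pseudo-absence
    cell scores, binarise every scenario surface at that threshold, record
    the area proportion p_i and whether the left-out cell was predicted
    present.  The exact tail of the success count gives the p-value.
    """
    if not occ.thinned:
        raise ValueError("occurrences must be thinned to unique cells first")
    cells = list(occ.cell_ids)
    n = len(cells)
    if n < 3:
        raise ValueError(f"jackknife needs >= 3 unique presence cells, got {n}")
    if train_scenario not in score_stacks:
        raise ValueError(f"train scenario {train_scenario!r} not among stacks")
    train = score_stacks[train_scenario]
    grid, mask = train.grid, train.mask

    if calibrator is None:
        def calibrator(training, pa_sets, stacks, rep_seed):
            rep = calibrate_replicate(
                training,
                pa_sets,
                stacks,
                families,
                n_runs,
                rep_seed,
                hyperparams=hyperparams,
                train_scenario=train_scenario,
            )
            return rep.maps

    rows = []
    binary_maps: dict[str, list[BinaryMap]] = {k: [] for k in score_stacks}
    successes: list[int] = []
    p_list: list[float] = []
    for i, left_out in enumerate(cells):
        training = [c for j, c in enumerate(cells) if j != i]
        b = bounds if bounds is not None else presence_distance_bounds(training, grid)
        pa_sets = build_pa_sets(
            grid,
            mask,
            training,
            families,
            n_pa_sets,
            b,
            seed_base=derive_seed(seed, 1, i),
            exclude_cells=[left_out],
        )
        maps = calibrator(training, pa_sets, score_stacks, derive_seed(seed, 2, i))
        ens = maps[train_scenario]
        pres_scores = ens.values_at(training)
        pa_cells = sorted({c for s in pa_sets for pa in s.values() for c in pa.cell_ids})
        abs_scores = ens.values_at(pa_cells)
        t, sens, spec = maxsensspec_threshold(pres_scores, abs_scores)
        rep_binaries = {label: binarize(m, t) for label, m in maps.items()}
        bin_cur = rep_binaries[train_scenario]
        p_i = area_weighted_presence_proportion(bin_cur)
        succ = int(bin_cur.values[left_out[0], left_out[1]] == 1.0)
        for label, bm in rep_binaries.items():
            binary_maps[label].append(bm)
        successes.append(succ)
        p_list.append(p_i)
        rows.append(
            {
                "left_out_row": left_out[0],
                "left_out_col": left_out[1],
                "threshold": t,
                "sensitivity": sens,
                "specificity": spec,
                "predicted_presence_proportion": p_i,
                "success": succ,
            }
        )
    D = int(sum(successes))
    if binomial == "poisson_binomial":
        p_value = poisson_binomial_pvalue(p_list, D)
    elif binomial == "homogeneous":
        p_value = homogeneous_binomial_pvalue(p_list, D)
    else:
        raise ValueError(f"unknown binomial mode {binomial!r}")
    report = JackknifeReport(
        rows=pd.DataFrame(rows), n=n, D=D, p_value=p_value, binomial_mode=binomial
    )
    return JackknifeResult(report=report, binary_maps=binary_maps, success_flags=successes)
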