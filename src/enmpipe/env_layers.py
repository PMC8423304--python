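"""Environmental raster stacks and their PCA reduction.

The pipeline reduces two blocks of environmental layers — ~19 correlated
bioclimatic surfaces and ~10 edaphic/topographic surfaces — to a handful of
principal-component scores that serve as model predictors.  Because the
variables mix incommensurate units (temperature, precipitation, soil
fractions, elevation), the PCA is computed on the correlation matrix:
each variable is standardised to zero mean and unit variance over the valid
cells before the eigendecomposition.

Future-scenario stacks are never re-fitted.  The transform fitted on the
current scenario (its means, standard deviations and loadings) is projected
onto the future layers, which preserves the correspondence of component
axes across scenarios.  Edaphic/topographic axes are treated as constant in
time and reused unchanged for every scenario.

Axis counts can be fixed integers or chosen by the broken-stick rule:
retain the leading axes whose observed eigenvalue proportion exceeds the
broken-stick null expectation ``b_k = (1/p) * sum_{i=k..p} 1/i``.

Rasters are read and written as single-band ESRI ASCII grids (plain text,
``.asc``), one file per layer; the layer name is the file stem.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .grids import WGS84, GridSpec
from .utils import logger

DEFAULT_NODATA = -9999.0


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    """Read a single-band ESRI ASCII grid.

    Returns the grid geometry and a float64 array with NoData cells set to
    NaN.  Only corner-registered headers (``xllcorner``/``yllcorner``) and a
    single ``cellsize`` are supported.
    """
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            m = re.match(r"^\s*([A-Za-z_]+)\s+(-?[\d.eE+]+)\s*$", line)
            if m and not data_lines:
                header[m.group(1).lower()] = float(m.group(2))
            elif line.strip():
                data_lines.append(line)
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    missing = required - header.keys()
    if missing:
        raise ValueError(f"{path}: ASCII grid header missing {sorted(missing)}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    values = np.loadtxt(data_lines, dtype=float, ndmin=2)
    if values.shape != (n_rows, n_cols):
        raise ValueError(
            f"{path}: data shape {values.shape} does not match header "
            f"({n_rows}, {n_cols})"
        )
    values[values == nodata] = np.nan
    grid = GridSpec(
        west=header["xllcorner"],
        north=header["yllcorner"] + n_rows * cell,
        cell_deg=cell,
        n_rows=n_rows,
        n_cols=n_cols,
        crs=WGS84,
    )
    return grid, values


def write_ascii_grid(
    path: str | Path,
    grid: GridSpec,
    values: np.ndarray,
    nodata: float = DEFAULT_NODATA,
) -> None:
    """Write a single-band ESRI ASCII grid; NaN becomes the NoData value."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"values shape {values.shape} != grid shape {grid.shape}")
    out = np.where(np.isnan(values), nodata, values)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.west!r}\n"
        f"yllcorner {grid.south!r}\n"
        f"cellsize {grid.cell_deg!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


# ---------------------------------------------------------------------------
# EnvStack
# ---------------------------------------------------------------------------

@dataclass
class EnvStack:
    """A co-registered stack of named environmental layers for one scenario.

    ``values`` has shape ``(n_layers, n_rows, n_cols)`` with NaN as the
    missing-data sentinel.  On construction the valid-cell mask is made
    common to all layers: a cell that is NoData in any layer becomes NoData
    in every layer, so all downstream surfaces share one mask.
    """

    grid: GridSpec
    layer_names: list[str]
    values: np.ndarray
    scenario_label: str = "current"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D (n_layers, n_rows, n_cols)")
        if self.values.shape[0] != len(self.layer_names):
            raise ValueError("number of layers does not match layer_names")
        if self.values.shape[1:] != self.grid.shape:
            raise ValueError(
                f"layer shape {self.values.shape[1:]} != grid shape {self.grid.shape}"
            )
        dupes = {n for n in self.layer_names if self.layer_names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate layer names: {sorted(dupes)}")
        # missing-data propagation: invalid anywhere -> invalid everywhere
        invalid = ~np.all(np.isfinite(self.values), axis=0)
        if invalid.any():
            self.values[:, invalid] = np.nan

    # -- accessors ----------------------------------------------------------

    @property
    def n_layers(self) -> int:
        return len(self.layer_names)

    @property
    def mask(self) -> np.ndarray:
        """Boolean valid-cell mask, shared by all layers."""
        return np.isfinite(self.values[0]) if self.n_layers else np.ones(self.grid.shape, bool)

    def layer(self, name: str) -> np.ndarray:
        try:
            i = self.layer_names.index(name)
        except ValueError:
            raise KeyError(f"no layer named {name!r}") from None
        return self.values[i]

    def subset(self, names: Sequence[str]) -> "EnvStack":
        """A new stack restricted to ``names``, in the given order."""
        missing = [n for n in names if n not in self.layer_names]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        idx = [self.layer_names.index(n) for n in names]
        return EnvStack(
            grid=self.grid,
            layer_names=list(names),
            values=self.values[idx].copy(),
            scenario_label=self.scenario_label,
        )

    def values_at(self, cells: Sequence[tuple[int, int]]) -> np.ndarray:
        """Layer values at given (row, col) cells, shape (n_cells, n_layers)."""
        cells = np.atleast_2d(np.asarray(cells, dtype=int))
        return self.values[:, cells[:, 0], cells[:, 1]].T

    def table(self) -> np.ndarray:
        """Valid-cell design matrix, shape (n_valid, n_layers)."""
        m = self.mask
        return self.values[:, m].T


def read_stack(paths: Iterable[str | Path], scenario_label: str = "current") -> EnvStack:
    """Read co-registered single-band ASCII rasters into one stack.

    Layer names come from the file stems.  All rasters must share the same
    grid geometry; the valid-cell mask is the intersection of the per-layer
    valid cells.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no raster paths given")
    names: list[str] = []
    layers: list[np.ndarray] = []
    grid: GridSpec | None = None
    for p in paths:
        g, vals = read_ascii_grid(p)
        if grid is None:
            grid = g
        elif not grid.matches(g):
            raise ValueError(f"grid mismatch: layer {p.stem!r} ({p}) does not match {paths[0].stem!r}")
        if p.stem in names:
            raise ValueError(f"duplicate layer name: {p.stem!r}")
        names.append(p.stem)
        layers.append(vals)
    assert grid is not None
    return EnvStack(grid=grid, layer_names=names, values=np.stack(layers), scenario_label=scenario_label)


def write_stack(stack: EnvStack, directory: str | Path) -> list[Path]:
    """Write each layer as ``<directory>/<layer>.asc``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for name, vals in zip(stack.layer_names, stack.values):
        p = directory / f"{name}.asc"
        write_ascii_grid(p, stack.grid, vals)
        out.append(p)
    return out


def concat_stacks(stacks: Sequence[EnvStack], prefixes: Sequence[str] | None = None) -> EnvStack:
    """Concatenate stacks on the same grid, optionally prefixing layer names.

    Used to join climate and edaphic PCA score stacks into one predictor
    stack (e.g. prefixes ``("clim", "eda")`` yield ``clim_PC1, ..., eda_PC1,
    ...``).
    """
    if not stacks:
        raise ValueError("no stacks to concatenate")
    base = stacks[0]
    names: list[str] = []
    vals: list[np.ndarray] = []
    for i, s in enumerate(stacks):
        if not s.grid.matches(base.grid):
            raise ValueError("cannot concatenate stacks on different grids")
        pre = f"{prefixes[i]}_" if prefixes else ""
        names.extend(pre + n for n in s.layer_names)
        vals.append(s.values)
    return EnvStack(
        grid=base.grid,
        layer_names=names,
        values=np.concatenate(vals),
        scenario_label=base.scenario_label,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCATransform:
    """A fitted correlation-matrix PCA for one variable block.

    Stores the standardisation constants and the full loading matrix so the
    identical linear map can be re-applied to future-scenario layers without
    re-fitting.  ``loadings`` is (n_variables, n_components) with orthonormal
    columns; ``eigenvalue_proportions`` is the proportion of total variance
    per component (non-increasing, sums to 1).
    """

    block_label: str
    variable_names: list[str]
    variable_means: np.ndarray
    variable_sds: np.ndarray
    loadings: np.ndarray
    eigenvalue_proportions: np.ndarray
    n_retained: int

    def __post_init__(self) -> None:
        self.variable_means = np.asarray(self.variable_means, dtype=float)
        self.variable_sds = np.asarray(self.variable_sds, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.eigenvalue_proportions = np.asarray(self.eigenvalue_proportions, dtype=float)
        if not 1 <= self.n_retained <= len(self.variable_names):
            raise ValueError("n_retained out of range")

    def to_dict(self) -> dict:
        return {
            "block_label": self.block_label,
            "variable_names": self.variable_names,
            "variable_means": self.variable_means.tolist(),
            "variable_sds": self.variable_sds.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalue_proportions": self.eigenvalue_proportions.tolist(),
            "n_retained": self.n_retained,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCATransform":
        return cls(
            block_label=d["block_label"],
            variable_names=list(d["variable_names"]),
            variable_means=np.array(d["variable_means"]),
            variable_sds=np.array(d["variable_sds"]),
            loadings=np.array(d["loadings"]),
            eigenvalue_proportions=np.array(d["eigenvalue_proportions"]),
            n_retained=int(d["n_retained"]),
        )


def broken_stick_select(eigenvalue_proportions: Sequence[float]) -> int:
    """Number of leading axes beating the broken-stick null expectation.

    For p axes the null expectation for axis k is
    ``b_k = (1/p) * sum_{i=k}^{p} 1/i``.  Retained axes are the maximal
    leading run with observed proportion strictly greater than ``b_k``;
    the floor is one axis.
    """
    props = np.asarray(eigenvalue_proportions, dtype=float)
    if props.size == 0:
        raise ValueError("empty eigenvalue proportions")
    p = props.size
    # b_k via reversed cumulative harmonic sum
    inv = 1.0 / np.arange(1, p + 1)
    b = np.cumsum(inv[::-1])[::-1] / p
    n = 0
    for k in range(p):
        if props[k] > b[k]:
            n += 1
        else:
            break
    return max(n, 1)


def fit_pca(
    stack: EnvStack,
    n_axes: int | str = "broken_stick",
    block_label: str = "climate",
) -> tuple[PCATransform, EnvStack]:
    """Correlation-matrix PCA of a stack; returns the transform and scores.

    Variables are standardised to zero mean / unit variance over valid
    cells.  ``n_axes`` is either a fixed axis count or ``"broken_stick"``.
    The returned score stack has layers ``PC1..PCk`` and is computed by
    re-applying the stored transform, so :func:`project_transform` on the
    training stack reproduces it exactly.
    """
    if stack.n_layers < 2:
        raise ValueError("PCA needs at least 2 layers")
    X = stack.table()
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 valid cells")
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    constant = [n for n, s in zip(stack.layer_names, sds) if s == 0.0]
    if constant:
        raise ValueError(f"constant layer(s) with zero variance: {constant}")
    Z = (X - means) / sds
    pca = PCA(n_components=min(X.shape[0], X.shape[1]), svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_.T.copy()
    # deterministic sign: dominant element of each loading column positive
    for j in range(loadings.shape[1]):
        dom = np.argmax(np.abs(loadings[:, j]))
        if loadings[dom, j] < 0:
            loadings[:, j] = -loadings[:, j]
    props = pca.explained_variance_ratio_.copy()
    if isinstance(n_axes, str):
        if n_axes != "broken_stick":
            raise ValueError(f"unknown axis-selection rule {n_axes!r}")
        k = broken_stick_select(props)
    else:
        k = int(n_axes)
        if not 1 <= k <= stack.n_layers:
            raise ValueError(f"n_axes={k} outside [1, {stack.n_layers}]")
        k = min(k, loadings.shape[1])
    transform = PCATransform(
        block_label=block_label,
        variable_names=list(stack.layer_names),
        variable_means=means,
        variable_sds=sds,
        loadings=loadings,
        eigenvalue_proportions=props,
        n_retained=k,
    )
    scores = project_transform(transform, stack)
    return transform, scores


def project_transform(transform: PCATransform, future_stack: EnvStack) -> EnvStack:
    """Apply a fitted transform's linear coefficients to another stack.

    Standardises the stack's layers with the *training* means and standard
    deviations and multiplies by the stored loadings, truncated to the
    retained components — no re-fit, so component axes correspond across
    scenarios.  The stack must contain exactly the transform's variables.
    """
    have = set(future_stack.layer_names)
    want = set(transform.variable_names)
    if have != want:
        missing = sorted(want - have)
        extra = sorted(have - want)
        raise ValueError(f"variable mismatch: missing {missing}, unexpected {extra}")
    ordered = future_stack.subset(transform.variable_names)
    k = transform.n_retained
    nr, nc = ordered.grid.shape
    scores = np.full((k, nr, nc), np.nan)
    m = ordered.mask
    Z = (ordered.values[:, m].T - transform.variable_means) / transform.variable_sds
    S = Z @ transform.loadings[:, :k]
    for j in range(k):
        scores[j, m] = S[:, j]
    return EnvStack(
        grid=ordered.grid,
        layer_names=[f"PC{j + 1}" for j in range(k)],
        values=scores,
        scenario_label=future_stack.scenario_label,
    )
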