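"""Scenario discovery on the threshold-analysis output.

Two steps borrowed from robust decision making:

1. rank the experimental factors by how strongly they drive the predicted
   cost-effectiveness status, using a seeded random forest's mean decrease in
   Gini impurity;
2. summarize the response with a locally weighted (tricube, degree-1)
   regression surface of net monetary benefit over the top-3 factors on an
   evenly spaced grid, conditioned on the best-case CRC sensitivity, with
   iso-NMB contour lines (including the colonoscopy reference level) that
   partition the map into noninferior/inferior regions.

The screening interval takes three discrete levels, so the 3-D surface is
realized as one 2-D (cost x AA sensitivity) panel per interval with the grid
budget split evenly across panels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import ConfigurationError, DegenerateLabelError

PREDICTORS = ("cost", "aa_sens", "interval", "model", "crc_sens")
CATEGORICAL = ("interval", "model")


@dataclass(frozen=True)
class ImportanceRanking:
    """Factors ordered by descending mean decrease in Gini importance."""

    entries: tuple[tuple[str, float, int], ...]  # (variable, score, rank)

    @property
    def order(self) -> list[str]:
        return [name for name, _, _ in self.entries]

    def score(self, name: str) -> float:
        for var, s, _ in self.entries:
            if var == name:
                return s
        raise KeyError(name)

    def top(self, k: int) -> list[str]:
        return self.order[:k]


def rank_importance(table: pd.DataFrame, label: str | np.ndarray = "cost_effective",
                    rf_config: Optional[dict] = None,
                    seed: int = 0) -> ImportanceRanking:
    """Seeded random-forest Gini importance of the design factors.

    Categorical factors (interval, model) are one-hot encoded and their
    importances summed back to the factor.  Raises
    :class:`DegenerateLabelError` when the label has a single class.
    """
    y = table[label].to_numpy() if isinstance(label, str) else np.asarray(label)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelError(
            "cost-effectiveness label contains a single class; importance "
            "ranking is undefined")
    predictors = [p for p in PREDICTORS if p in table.columns]
    if not predictors:
        raise ConfigurationError("table has none of the design-factor columns")
    cols: list[np.ndarray] = []
    owner: list[str] = []
    for p in predictors:
        if p in CATEGORICAL:
            dummies = pd.get_dummies(table[p], prefix=p)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(float))
                owner.append(p)
        else:
            cols.append(table[p].to_numpy(float))
            owner.append(p)
    X = np.column_stack(cols)
    cfg = {"n_estimators": 500, "random_state": seed}
    cfg.update(rf_config or {})
    rf = RandomForestClassifier(**cfg)
    rf.fit(X, y)
    scores = {p: 0.0 for p in predictors}
    for imp, p in zip(rf.feature_importances_, owner):
        scores[p] += float(imp)
    ordered = sorted(scores.items(), key=lambda kv: -kv[1])
    entries = tuple((name, score, rank + 1)
                    for rank, (name, score) in enumerate(ordered))
    return ImportanceRanking(entries)


# ---------------------------------------------------------------------------
# locally weighted regression surface

def _loess2d(x: np.ndarray, y: np.ndarray, xq: np.ndarray,
             span: float = 0.5) -> np.ndarray:
    """Tricube-weighted degree-1 local regression of y on 2-D x at queries xq.

    Distances are scaled per dimension by the data range; the bandwidth at
    each query is the distance to the ceil(span*n)-th nearest point.
    Reproduces an exactly linear response exactly (weighted least squares of
    linear data is that same linear function).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.shape[0]
    scale = np.ptp(x, axis=0)
    scale[scale == 0] = 1.0
    xs = x / scale
    k = max(min(int(math.ceil(span * n)), n), 3)
    out = np.empty(len(xq))
    xqs = np.asarray(xq, float) / scale
    for i, q in enumerate(xqs):
        d = np.hypot(*(xs - q).T)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            h = d.max() or 1.0
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        if w.sum() == 0:
            w = np.ones(n)
        A = np.column_stack([np.ones(n), xs[:, 0], xs[:, 1]])
        Aw = A * w[:, None]
        beta, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ y, rcond=None)
        out[i] = beta[0] + beta[1] * q[0] + beta[2] * q[1]
    return out


@dataclass
class NMBSurface:
    """Smoothed NMB over (interval panel) x (cost, AA sensitivity) grid."""

    table: pd.DataFrame          # columns: interval, cost, aa_sens, nmb_smoothed
    panel_var: str
    axis_vars: tuple[str, str]
    grid_shape: tuple[int, int]  # (n_cost, n_aa) per panel
    conditioning: dict
    reference_level: Optional[float] = None

    def panel(self, level: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(cost axis, aa axis, z[cost_i, aa_j]) for one interval panel."""
        sub = self.table[self.table[self.panel_var] == level]
        xs = np.sort(sub[self.axis_vars[0]].unique())
        ys = np.sort(sub[self.axis_vars[1]].unique())
        z = (sub.pivot(index=self.axis_vars[0], columns=self.axis_vars[1],
                       values="nmb_smoothed")
             .loc[xs, ys].to_numpy())
        return xs, ys, z


def fit_nmb_surface(table: pd.DataFrame,
                    vars: Sequence[str] = ("cost", "aa_sens", "interval"),
                    grid_n: int = 10_000,
                    conditioning: Optional[dict] = None,
                    span: float = 0.5,
                    value_col: str = "nmb") -> NMBSurface:
    """Locally weighted NMB surface on an evenly spaced grid of ~grid_n points.

    ``conditioning`` filters the table (default: CRC sensitivity at its top
    level, 0.92); replicate rows (e.g. several natural-history parameter
    sets) are averaged before smoothing.  The discrete variable among
    ``vars`` (interval) indexes panels; the two continuous variables span
    each panel's axes.
    """
    conditioning = {"crc_sens": 0.92} if conditioning is None else conditioning
    vars = tuple(vars)
    for v in vars:
        if v not in table.columns:
            raise ConfigurationError(f"surface variable '{v}' not in table")
    sub = table.copy()
    for col, val in conditioning.items():
        sub = sub[np.isclose(sub[col].astype(float), float(val))]
        if sub.empty:
            raise ConfigurationError(
                f"conditioning {col}={val} matches no rows in the table")
    # average across replicates (e.g. models) at identical factor settings
    sub = sub.groupby(list(vars), as_index=False)[value_col].mean()

    panel_var = "interval" if "interval" in vars else vars[-1]
    axis_vars = tuple(v for v in vars if v != panel_var)
    levels = np.sort(sub[panel_var].unique())
    per_panel = grid_n / len(levels)
    side = int(round(math.sqrt(per_panel)))
    if side * side * len(levels) != grid_n:
        warnings.warn(
            f"grid_n={grid_n} is not a {len(levels)}x(k x k) lattice; using "
            f"{side}x{side} per panel ({side * side * len(levels)} points)",
            stacklevel=2)
    frames = []
    for level in levels:
        panel = sub[sub[panel_var] == level]
        x = panel[list(axis_vars)].to_numpy(float)
        y = panel[value_col].to_numpy(float)
        ax0 = np.linspace(x[:, 0].min(), x[:, 0].max(), side)
        ax1 = np.linspace(x[:, 1].min(), x[:, 1].max(), side)
        g0, g1 = np.meshgrid(ax0, ax1, indexing="ij")
        xq = np.column_stack([g0.ravel(), g1.ravel()])
        z = _loess2d(x, y, xq, span=span)
        if not np.all(np.isfinite(z)):
            raise RuntimeError("smoothed surface contains non-finite values")
        frames.append(pd.DataFrame({
            panel_var: level,
            axis_vars[0]: xq[:, 0],
            axis_vars[1]: xq[:, 1],
            "nmb_smoothed": z,
        }))
    return NMBSurface(pd.concat(frames, ignore_index=True), panel_var,
                      axis_vars, (side, side), dict(conditioning))


@dataclass
class ContourSet:
    """Iso-NMB polylines per level and panel, in data coordinates."""

    levels: tuple[float, ...]
    # {level: {panel level: [array of (axis0, axis1) points, ...]}}
    polylines: dict[float, dict[float, list[np.ndarray]]]
    reference_level: Optional[float] = None


def extract_contours(surface: NMBSurface, levels: Sequence[float],
                     reference_level: Optional[float] = None) -> ContourSet:
    """Marching-squares iso-lines of the smoothed surface at each level.

    Levels outside a panel's value range yield empty polyline lists.  The
    colonoscopy reference level, when supplied, is appended so the map can be
    partitioned into noninferior/inferior regions.
    """
    from skimage import measure

    levels = sorted(set(float(l) for l in levels)
                    | ({float(reference_level)} if reference_level is not None
                       else set()))
    panel_levels = np.sort(surface.table[surface.panel_var].unique())
    polylines: dict[float, dict[float, list[np.ndarray]]] = {}
    for level in levels:
        per_panel: dict[float, list[np.ndarray]] = {}
        for pl in panel_levels:
            xs, ys, z = surface.panel(pl)
            lines = []
            if z.min() <= level <= z.max():
                for contour in measure.find_contours(z, level):
                    ci = np.interp(contour[:, 0], np.arange(len(xs)), xs)
                    cj = np.interp(contour[:, 1], np.arange(len(ys)), ys)
                    lines.append(np.column_stack([ci, cj]))
            per_panel[float(pl)] = lines
        polylines[level] = per_panel
    return ContourSet(tuple(levels), polylines, reference_level)


def contours_to_json(contours: ContourSet) -> dict:
    return {
        "reference_level": contours.reference_level,
        "levels": {
            str(level): {
                str(panel): [line.tolist() for line in lines]
                for panel, lines in per_panel.items()
            }
            for level, per_panel in contours.polylines.items()
        },
    }
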