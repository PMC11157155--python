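"""Parameter-space sweep and confidence-interval fitting.

The method mirrors how poorly constrained fluxes and fractionations are
estimated in isotope box modelling: lay a Cartesian grid over the unknown
parameters, compute the steady state at every node, and keep the nodes
whose predicted compositions fall inside every observed confidence
interval.  No continuous optimisation is involved — the accepted *region*
is the result, summarised by per-axis marginal ranges and a representative
(coordinate-wise median) node.

Axes come in two flavours.  A :class:`FractionationAxis` sweeps the per-mil
amplitude on one edge, optionally driving a paired edge at the opposite
sign (the split convention used for exchange fluxes with dead-end
reservoirs).  A :class:`FluxAxis` sweeps a rate applied to one or more
edges simultaneously, with optional compensating edges that absorb the rate
change so every box stays mass-balanced at every node.

Because the steady state is linear in delta, the sweep factorises: the rate
matrix depends only on the flux axes while fractionation amplitudes enter
the right-hand side linearly, so each flux combination is solved once for
all fractionation combinations at once.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import DietForcing, simulate
from .model import BoxModel, FluxSpec, ModelError, delta_to_alpha
from .observations import ObservationTable

__all__ = [
    "FractionationAxis",
    "FluxAxis",
    "SweepResult",
    "FitResult",
    "CalibrationResult",
    "sweep",
    "ci_fit",
    "renal_sensitivity",
    "calibrate_switch",
    "apply_axis_value",
    "axis_from_dict",
]

Edge = tuple[str, str]


def _axis_values(lo: float, hi: float, n_points: int, scale: str) -> np.ndarray:
    if not lo < hi:
        raise ValueError(f"degenerate axis range [{lo}, {hi}]")
    if n_points < 2:
        raise ValueError(f"axis needs n_points >= 2, got {n_points}")
    if scale == "linear":
        return np.linspace(lo, hi, n_points)
    if scale == "log":
        if lo <= 0:
            raise ValueError("log-scaled axis needs lo > 0")
        return np.geomspace(lo, hi, n_points)
    raise ValueError(f"unknown scale {scale!r}")


@dataclass(frozen=True)
class FractionationAxis:
    """Sweep the per-mil fractionation amplitude of one flux edge.

    ``paired_edge``, if given, receives the opposite amplitude (split
    convention: an exchange pair fractionates symmetrically on influx and
    efflux).
    """

    name: str
    edge: Edge
    lo: float
    hi: float
    n_points: int
    scale: str = "linear"
    paired_edge: Edge | None = None

    def values(self) -> np.ndarray:
        return _axis_values(self.lo, self.hi, self.n_points, self.scale)


@dataclass(frozen=True)
class FluxAxis:
    """Sweep a rate (ug/day) applied to every edge in ``edges``.

    Each edge in ``compensate`` has its base rate shifted by the negative
    of the change applied to the swept edges, keeping all boxes balanced
    (e.g. raising the integument loss lowers the endogenous loss to the
    intestine and the fecal through-flux by the same amount).
    """

    name: str
    edges: tuple[Edge, ...]
    lo: float
    hi: float
    n_points: int
    scale: str = "log"
    compensate: tuple[Edge, ...] = ()

    def values(self) -> np.ndarray:
        return _axis_values(self.lo, self.hi, self.n_points, self.scale)


Axis = FractionationAxis | FluxAxis

GRID_WARN = 10**6


@dataclass
class SweepResult:
    """Steady states on the full grid, row-major over axes as declared."""

    axes: list[Axis]
    values: list[np.ndarray]           # per-axis grid values
    boxes: list[str]                   # finite boxes, column order of `deltas`
    deltas: np.ndarray                 # shape (*grid_shape, n_boxes)
    diet_delta: float

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(v) for v in self.values)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    def node_params(self, index: tuple[int, ...]) -> dict[str, float]:
        return {ax.name: float(v[i]) for ax, v, i in zip(self.axes, self.values, index)}

    def node_steady_state(self, index: tuple[int, ...]) -> dict[str, float]:
        return dict(zip(self.boxes, self.deltas[index]))


def _modified_fluxes(model: BoxModel, rate_overrides: dict[Edge, float]) -> list[FluxSpec]:
    out = []
    for f in model.fluxes:
        if f.edge in rate_overrides:
            r = rate_overrides[f.edge]
            if r < 0:
                raise ModelError(f"axis drives flux {f.source}->{f.target} negative ({r:.3g})")
            out.append(FluxSpec(f.source, f.target, r, f.alpha))
        else:
            out.append(f)
    return out


def _check_balanced(model: BoxModel, fluxes: list[FluxSpec], context: str) -> None:
    imbalance: dict[str, float] = {b: 0.0 for b in model.finite_boxes}
    for f in fluxes:
        if f.target in imbalance:
            imbalance[f.target] += f.rate
        if f.source in imbalance:
            imbalance[f.source] -= f.rate
    bad = {k: v for k, v in imbalance.items() if abs(v) > 1e-6}
    if bad:
        raise ModelError(f"sweep node unbalanced ({context}): {bad}")


def sweep(model: BoxModel, axes: Sequence[Axis], diet_delta: float) -> SweepResult:
    """Steady state at every node of the Cartesian grid over ``axes``."""
    axes = list(axes)
    values = [ax.values() for ax in axes]
    shape = tuple(len(v) for v in values)
    if int(np.prod(shape)) > GRID_WARN:
        import warnings

        warnings.warn(f"sweep grid has {int(np.prod(shape))} nodes (> {GRID_WARN})")

    known_edges = {f.edge for f in model.fluxes}
    for ax in axes:
        edges = ax.edges + ax.compensate if isinstance(ax, FluxAxis) else (
            (ax.edge,) + ((ax.paired_edge,) if ax.paired_edge else ())
        )
        for e in edges:
            if e not in known_edges:
                raise ModelError(f"axis {ax.name!r} references unknown flux {e[0]}->{e[1]}")

    flux_pos = [i for i, ax in enumerate(axes) if isinstance(ax, FluxAxis)]
    frac_pos = [i for i, ax in enumerate(axes) if isinstance(ax, FractionationAxis)]

    boxes = model.finite_boxes
    idx = {b: i for i, b in enumerate(boxes)}
    mass = {b: model.compartment(b).mass for b in boxes}
    n = len(boxes)

    frac_edges: set[Edge] = set()
    for i in frac_pos:
        ax = axes[i]
        frac_edges.add(ax.edge)
        if ax.paired_edge:
            frac_edges.add(ax.paired_edge)

    # fractionation combinations, row-major in declared axis order
    frac_shape = tuple(shape[i] for i in frac_pos)
    frac_grids = np.meshgrid(*[values[i] for i in frac_pos], indexing="ij") if frac_pos else []
    n_frac = int(np.prod(frac_shape)) if frac_pos else 1

    base_rates = {f.edge: f.rate for f in model.fluxes}
    deltas = np.empty(shape + (n,))

    for combo in itertools.product(*[range(shape[i]) for i in flux_pos]):
        overrides: dict[Edge, float] = {}
        for pos, k in zip(flux_pos, combo):
            ax = axes[pos]
            v = float(values[pos][k])
            for e in ax.edges:
                overrides[e] = v
            change = v - base_rates[ax.edges[0]]
            for e in ax.compensate:
                overrides[e] = overrides.get(e, base_rates[e]) - change
        fluxes = _modified_fluxes(model, overrides)
        _check_balanced(model, fluxes, context=f"flux indices {combo}")

        A = np.zeros((n, n))
        b0 = np.zeros(n)       # constant offsets from non-swept fractionations
        b_src = np.zeros(n)
        coef = {e: np.zeros(n) for e in frac_edges}  # d(rhs)/d(amplitude on edge e)
        for f in fluxes:
            swept = f.edge in frac_edges
            if f.target in idx:
                i = idx[f.target]
                if f.source in idx:
                    A[i, idx[f.source]] += f.rate / mass[f.target]
                elif model.compartment(f.source).role == "source":
                    b_src[i] += f.rate / mass[f.target]
                if swept:
                    coef[f.edge][i] += f.rate / mass[f.target]
                else:
                    b0[i] += f.rate * f.cap_delta / mass[f.target]
            if f.source in idx:
                j = idx[f.source]
                A[j, j] -= f.rate / mass[f.source]
                if swept:
                    coef[f.edge][j] -= f.rate / mass[f.source]
                else:
                    b0[j] -= f.rate * f.cap_delta / mass[f.source]

        # rhs matrix over all fractionation combinations
        B = np.tile((b0 + b_src * diet_delta)[:, None], (1, n_frac))
        for g, pos in zip(frac_grids, frac_pos):
            ax = axes[pos]
            amp = g.reshape(-1)
            B += np.outer(coef[ax.edge], amp)
            if ax.paired_edge:
                B -= np.outer(coef[ax.paired_edge], amp)
        sol = np.linalg.solve(A, -B)          # (n, n_frac)

        # scatter into the full grid: fixed flux indices, all frac indices
        block = sol.T.reshape(frac_shape + (n,)) if frac_pos else sol.T.reshape((n,))
        index: list = [slice(None)] * len(shape)
        for pos, k in zip(flux_pos, combo):
            index[pos] = k
        # `block` axes follow frac_pos order; grid slots left as slices follow
        # declared order restricted to frac axes, which is the same order.
        deltas[tuple(index)] = block
    return SweepResult(axes=axes, values=values, boxes=boxes, deltas=deltas, diet_delta=diet_delta)


@dataclass
class FitResult:
    """Accepted region of a sweep under confidence-interval constraints."""

    sweep: SweepResult
    accepted: np.ndarray                       # bool, grid shape
    constraints: list[str]                     # constrained compartments used
    representative: tuple[int, ...] | None     # grid index, None if empty
    diagnostics: pd.DataFrame | None = None    # populated when acceptance is empty

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.sum())

    @property
    def accepted_fraction(self) -> float:
        return self.n_accepted / self.accepted.size

    def axis_ranges(self) -> dict[str, tuple[float, float]]:
        """Per-axis marginal [min, max] of accepted node values."""
        out = {}
        if self.n_accepted == 0:
            return {ax.name: (np.nan, np.nan) for ax in self.sweep.axes}
        where = np.nonzero(self.accepted)
        for d, ax in enumerate(self.sweep.axes):
            vals = self.sweep.values[d][where[d]]
            out[ax.name] = (float(vals.min()), float(vals.max()))
        return out

    def representative_params(self) -> dict[str, float]:
        if self.representative is None:
            raise ValueError("empty accepted region has no representative set")
        return self.sweep.node_params(self.representative)

    def representative_steady_state(self) -> dict[str, float]:
        if self.representative is None:
            raise ValueError("empty accepted region has no representative set")
        return self.sweep.node_steady_state(self.representative)

    def accepted_table(self, max_rows: int | None = None) -> pd.DataFrame:
        """Accepted nodes as a table of axis values plus predicted deltas."""
        where = np.nonzero(self.accepted)
        rows = len(where[0]) if max_rows is None else min(max_rows, len(where[0]))
        data = {}
        for d, ax in enumerate(self.sweep.axes):
            data[ax.name] = self.sweep.values[d][where[d][:rows]]
        for j, b in enumerate(self.sweep.boxes):
            data[f"delta_{b}"] = self.sweep.deltas[tuple(w[:rows] for w in where) + (j,)]
        return pd.DataFrame(data)


def ci_fit(grid: SweepResult, observations: ObservationTable) -> FitResult:
    """Keep grid nodes whose steady state honours every observed CI.

    A node is accepted iff ``|predicted - observed| <= ci_halfwidth`` for
    every non-excluded observation.  An empty acceptance is a valid result;
    its diagnostics name the least-violating node and the worst observation.
    """
    constrained = [o for o in observations.constrained]
    if not constrained:
        raise ValueError("no constrained observations to fit against")

    shape = grid.shape
    accepted = np.ones(shape, dtype=bool)
    worst = np.full(shape, -np.inf)  # per-node worst violation, for diagnostics
    used = []
    box_idx = {b: i for i, b in enumerate(grid.boxes)}
    for o in constrained:
        if o.compartment in box_idx:
            viol = np.abs(grid.deltas[..., box_idx[o.compartment]] - o.delta) - o.ci_halfwidth
        else:
            # source compartment: predicted composition is the prescribed diet
            viol = np.full(shape, abs(grid.diet_delta - o.delta) - o.ci_halfwidth)
        used.append(o.compartment)
        accepted &= viol <= 0
        worst = np.maximum(worst, viol)

    representative = None
    diagnostics = None
    if accepted.any():
        where = np.nonzero(accepted)
        target = [np.median(w) for w in where]
        # snap to the nearest accepted node in index space
        dist = sum((w - t) ** 2 for w, t in zip(where, target))
        k = int(np.argmin(dist))
        representative = tuple(int(w[k]) for w in where)
    else:
        flat = int(np.argmin(worst.reshape(-1)))
        index = np.unravel_index(flat, shape)
        params = grid.node_params(index)
        per_obs = []
        for o in constrained:
            if o.compartment in box_idx:
                pred = float(grid.deltas[index + (box_idx[o.compartment],)])
            else:
                pred = grid.diet_delta
            per_obs.append(
                {
                    "compartment": o.compartment,
                    "observed": o.delta,
                    "predicted": pred,
                    "ci_halfwidth": o.ci_halfwidth,
                    "violation": abs(pred - o.delta) - o.ci_halfwidth,
                    **params,
                }
            )
        diagnostics = pd.DataFrame(per_obs).sort_values("violation", ascending=False)
    return FitResult(
        sweep=grid,
        accepted=accepted,
        constraints=used,
        representative=representative,
        diagnostics=diagnostics,
    )


def renal_sensitivity(
    model: BoxModel,
    observations: ObservationTable,
    amplitudes: Sequence[float],
    edge: Edge = ("kidney", "urine"),
) -> pd.DataFrame:
    """Effect of the urinary fractionation amplitude on constrained boxes.

    For each per-mil amplitude, the steady state is recomputed with the
    urinary efflux carrying that fractionation and compared with the
    zero-amplitude baseline; reported is the maximum absolute shift across
    the constrained compartments.  The urinary flux is a ~7/1000 fraction
    of intake, so the leverage is small even at 1 per mil.
    """
    from .model import steady_state

    constrained = [
        o.compartment for o in observations.constrained
        if o.compartment in model.finite_boxes
    ]
    if not constrained:
        raise ValueError("no constrained finite boxes in observation table")
    diet = model.source.delta0 if model.source and model.source.delta0 is not None else 0.0

    def with_amp(amp: float) -> BoxModel:
        f = model.flux(*edge)
        return model.with_fluxes({edge: FluxSpec(f.source, f.target, f.rate, delta_to_alpha(amp))})

    base = steady_state(with_amp(0.0), diet)
    rows = []
    for amp in amplitudes:
        if not 0.0 <= amp <= 1.0:
            raise ValueError(f"amplitude {amp} outside the explored range [0, 1] per mil")
        ss = steady_state(with_amp(amp), diet)
        shifts = {b: ss[b] - base[b] for b in constrained}
        worst = max(shifts, key=lambda b: abs(shifts[b]))
        rows.append(
            {
                "amplitude": amp,
                "max_abs_change": abs(shifts[worst]),
                "most_affected_box": worst,
            }
        )
    return pd.DataFrame(rows)


def apply_axis_value(model: BoxModel, axis: Axis, value: float) -> BoxModel:
    """A model copy with one axis pinned at ``value``.

    Flux axes move their edges (and compensating edges) in rates;
    fractionation axes replace the fractionation amplitude on their edge
    (and the opposite amplitude on a paired edge).
    """
    if isinstance(axis, FluxAxis):
        overrides = {e: value for e in axis.edges}
        change = value - model.flux(*axis.edges[0]).rate
        for e in axis.compensate:
            overrides[e] = model.flux(*e).rate - change
        fluxes = {
            e: FluxSpec(e[0], e[1], r, model.flux(*e).alpha) for e, r in overrides.items()
        }
        return model.with_fluxes(fluxes)
    f = model.flux(*axis.edge)
    fluxes = {axis.edge: FluxSpec(f.source, f.target, f.rate, delta_to_alpha(value))}
    if axis.paired_edge:
        g = model.flux(*axis.paired_edge)
        fluxes[axis.paired_edge] = FluxSpec(g.source, g.target, g.rate, delta_to_alpha(-value))
    return model.with_fluxes(fluxes)


def axis_from_dict(doc: dict) -> Axis:
    """Build an axis from a plain mapping (the axes-YAML schema).

    ``kind: fractionation`` needs ``edge`` (and optional ``paired_edge``);
    ``kind: flux`` needs ``edges`` (and optional ``compensate``).
    """
    kind = doc.get("kind")
    common = dict(
        name=doc["name"],
        lo=float(doc["lo"]),
        hi=float(doc["hi"]),
        n_points=int(doc["n_points"]),
        scale=doc.get("scale", "linear" if kind == "fractionation" else "log"),
    )
    if kind == "fractionation":
        paired = doc.get("paired_edge")
        return FractionationAxis(
            edge=tuple(doc["edge"]),
            paired_edge=tuple(paired) if paired else None,
            **common,
        )
    if kind == "flux":
        return FluxAxis(
            edges=tuple(tuple(e) for e in doc["edges"]),
            compensate=tuple(tuple(e) for e in doc.get("compensate", ())),
            **common,
        )
    raise ValueError(f"unknown axis kind {kind!r}")


@dataclass
class CalibrationResult:
    """Second-stage diet-switch calibration of one swept parameter."""

    axis: Axis
    values: np.ndarray
    chi2: np.ndarray
    accepted: np.ndarray     # bool: all observations within their CI
    best: float              # value minimising chi-square

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": self.values,
                "chi2": self.chi2,
                "accepted": self.accepted,
            }
        )


def calibrate_switch(
    model: BoxModel,
    axis: Axis,
    series: pd.DataFrame,
    forcing: DietForcing,
    dt: float = 0.1,
) -> CalibrationResult:
    """Filter an axis against a diet-switch time series.

    ``series`` is an observation-at-time table with columns
    ``day, compartment, delta66Zn, ci_halfwidth``.  For each axis value the
    model is re-simulated through the step switch and compared against the
    series; a value is accepted when every observation lies within its CI,
    and the chi-square over all observations ranks the values.

    This is the stage that discriminates slow-pool turnover: a steady-state
    fit cannot constrain a balanced exchange flux (the steady state is
    independent of it), but the transient after a switch is not.
    """
    if forcing.kind != "step":
        raise ValueError("switch calibration requires step forcing")
    required = {"day", "compartment", "delta66Zn", "ci_halfwidth"}
    if not required <= set(series.columns):
        raise ValueError(f"series needs columns {sorted(required)}")
    t_end = float(series["day"].max())
    if t_end <= 0:
        t_end = dt
    values = axis.values()
    chi2 = np.zeros(len(values))
    accepted = np.ones(len(values), dtype=bool)
    for k, v in enumerate(values):
        m = apply_axis_value(model, axis, float(v))
        traj = simulate(m, forcing, t_end=t_end + dt, dt=dt)
        for row in series.itertuples(index=False):
            pred = float(np.interp(row.day, traj.t, traj[row.compartment]))
            resid = pred - row.delta66Zn
            chi2[k] += (resid / row.ci_halfwidth) ** 2
            if abs(resid) > row.ci_halfwidth:
                accepted[k] = False
    best = float(values[int(np.argmin(chi2))])
    return CalibrationResult(axis=axis, values=values, chi2=chi2, accepted=accepted, best=best)
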