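"""Core domain types and linear-algebra engine for isotope box models.

A box model is a network of well-mixed zinc pools (compartments) exchanging
material through first-order fluxes.  Each directed flux i->j carries a
fractionation coefficient ``alpha`` close to 1; its per-mil expression is
``Delta = 1000 * ln(alpha)``.  Compositions are tracked in delta notation
(per mil vs. JMC-Lyon).  Under the delta-linear bookkeeping every flux
delivers ``delta_source + Delta`` to its target, which keeps the steady
state an exactly linear problem and the dynamics a linear ODE system

    M_i d(delta_i)/dt = sum_in F (delta_src + Delta_in)
                      - sum_out F (delta_i + Delta_out)

over the finite boxes (sources held fixed, sinks excluded).  An exact
ratio-based bookkeeping (fluxes carry ``ratio_source * alpha``) is offered
as a cross-check; the two differ by O(Delta^2 / 10^6).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "Compartment",
    "FluxSpec",
    "BoxModel",
    "SteadyState",
    "BalanceReport",
    "RelaxationMode",
    "ModelError",
    "load_model",
    "save_model",
    "validate_mass_balance",
    "steady_state",
    "residence_time",
    "relaxation_times",
    "relaxation_modes",
    "alpha_to_delta",
    "delta_to_alpha",
]

#: default tolerance for per-box flux imbalance, ug/day
BALANCE_TOL = 1e-6

ROLES = ("internal", "source", "sink", "accumulator")


class ModelError(ValueError):
    """Raised when a box model violates a structural invariant."""


def alpha_to_delta(alpha: float) -> float:
    """Per-mil expression of a fractionation coefficient, 1000*ln(alpha)."""
    return 1000.0 * math.log(alpha)


def delta_to_alpha(cap_delta: float) -> float:
    """Fractionation coefficient for a per-mil amplitude, exp(Delta/1000)."""
    return math.exp(cap_delta / 1000.0)


@dataclass(frozen=True)
class Compartment:
    """A named Zn pool.

    Parameters
    ----------
    name : str
        Identifier, unique within a model.
    mass : float or None
        Zn content in ug for finite boxes; ``None`` marks an infinite box
        (source or sink), which carries no evolving composition.
    role : {"internal", "source", "sink", "accumulator"}
        Sources emit at a prescribed delta and never receive; sinks receive
        and never emit.  Accumulators (feces, urine) are finite pass-through
        excreta pools whose efflux goes to a sink.
    delta0 : float or None
        Initial delta66Zn in per mil (sources: the prescribed diet value).
    """

    name: str
    mass: float | None = None
    role: str = "internal"
    delta0: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ModelError(f"unknown role {self.role!r} for box {self.name!r}")
        if self.infinite:
            if self.role in ("internal", "accumulator"):
                raise ModelError(f"finite role {self.role!r} requires a mass: {self.name!r}")
        else:
            if self.mass is None or self.mass <= 0:
                raise ModelError(f"box {self.name!r} needs mass > 0, got {self.mass!r}")
            if self.role in ("source", "sink"):
                raise ModelError(f"{self.role} box {self.name!r} must be infinite")

    @property
    def infinite(self) -> bool:
        return self.mass is None

    @property
    def finite(self) -> bool:
        return self.mass is not None


@dataclass(frozen=True)
class FluxSpec:
    """A directed Zn transfer with its isotope fractionation.

    ``rate`` is in ug/day; ``alpha`` is the fractionation coefficient of the
    transfer (dimensionless, ~1).  ``cap_delta`` (per mil) is derived as
    1000*ln(alpha) and stored for reporting.
    """

    source: str
    target: str
    rate: float
    alpha: float = 1.0
    cap_delta: float = field(init=False)

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ModelError(f"self-loop flux on {self.source!r}")
        if self.rate < 0:
            raise ModelError(
                f"negative rate {self.rate} on flux {self.source}->{self.target}"
            )
        if not (0.99 < self.alpha < 1.01):
            raise ModelError(
                f"alpha {self.alpha} outside sanity band (0.99, 1.01) "
                f"on flux {self.source}->{self.target}"
            )
        object.__setattr__(self, "cap_delta", alpha_to_delta(self.alpha))

    @property
    def edge(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass(frozen=True)
class BalanceReport:
    """Per-compartment flux imbalance (influx minus efflux, ug/day)."""

    imbalance: Mapping[str, float]
    tolerance: float = BALANCE_TOL

    @property
    def unbalanced(self) -> dict[str, float]:
        return {k: v for k, v in self.imbalance.items() if abs(v) > self.tolerance}

    @property
    def balanced(self) -> bool:
        return not self.unbalanced


@dataclass(frozen=True)
class SteadyState:
    """Map compartment -> delta66Zn (per mil) at t -> infinity."""

    deltas: Mapping[str, float]
    diet_delta: float

    def __getitem__(self, box: str) -> float:
        return self.deltas[box]

    def __iter__(self):
        return iter(self.deltas)

    def items(self):
        return self.deltas.items()


@dataclass(frozen=True)
class RelaxationMode:
    """One exponential mode of the whole system: -1/eigenvalue, in days."""

    time: float
    dominant_box: str


class BoxModel:
    """A validated compartment network with first-order fluxes.

    Construction validates structural invariants: unique names, known
    endpoints, no duplicate edges, at most one source, at least one sink,
    source-to-box connectivity, and accumulator wiring.  Mass balance is a
    separate reporting step (:func:`validate_mass_balance`) because the
    printed literature configuration of the rat model is deliberately
    shipped unbalanced.
    """

    def __init__(
        self,
        compartments: Iterable[Compartment],
        fluxes: Iterable[FluxSpec],
        name: str = "model",
        description: str = "",
    ) -> None:
        self.compartments = list(compartments)
        self.fluxes = list(fluxes)
        self.name = name
        self.description = description
        self._by_name = {c.name: c for c in self.compartments}
        self._validate()

    # -- structural validation -------------------------------------------

    def _validate(self) -> None:
        if len(self._by_name) != len(self.compartments):
            seen: set[str] = set()
            for c in self.compartments:
                if c.name in seen:
                    raise ModelError(f"duplicate compartment name {c.name!r}")
                seen.add(c.name)
        sources = [c for c in self.compartments if c.role == "source"]
        sinks = [c for c in self.compartments if c.role == "sink"]
        if len(sources) > 1:
            raise ModelError(f"at most one source allowed, got {[c.name for c in sources]}")
        if not sinks:
            raise ModelError("model needs at least one sink")

        edges: set[tuple[str, str]] = set()
        for f in self.fluxes:
            for end in f.edge:
                if end not in self._by_name:
                    raise ModelError(
                        f"flux {f.source}->{f.target} references unknown compartment {end!r}"
                    )
            if f.edge in edges:
                raise ModelError(f"duplicate flux edge {f.source}->{f.target}")
            edges.add(f.edge)
            if self._by_name[f.target].role == "source":
                raise ModelError(f"flux into source box: {f.source}->{f.target}")
            if self._by_name[f.source].role == "sink":
                raise ModelError(f"flux out of sink box: {f.source}->{f.target}")

        # connectivity: every finite box reachable from the source
        if sources:
            reached = {sources[0].name}
            frontier = [sources[0].name]
            out = {}
            for f in self.fluxes:
                out.setdefault(f.source, []).append(f.target)
            while frontier:
                nxt = []
                for u in frontier:
                    for v in out.get(u, ()):
                        if v not in reached:
                            reached.add(v)
                            nxt.append(v)
                frontier = nxt
            missing = [c.name for c in self.compartments if c.finite and c.name not in reached]
            if missing:
                raise ModelError(f"source not connected to finite box(es): {missing}")
        elif any(c.finite for c in self.compartments):
            raise ModelError("source not connected: model has finite boxes but no source")

        for c in self.compartments:
            if c.role == "accumulator":
                inflows = [f for f in self.fluxes if f.target == c.name]
                outflows = [f for f in self.fluxes if f.source == c.name]
                if not inflows:
                    raise ModelError(f"accumulator {c.name!r} has no influx")
                if len(outflows) != 1 or self._by_name[outflows[0].target].role != "sink":
                    raise ModelError(
                        f"accumulator {c.name!r} must have exactly one efflux to a sink"
                    )

    # -- accessors -------------------------------------------------------

    def compartment(self, name: str) -> Compartment:
        try:
            return self._by_name[name]
        except KeyError:
            raise ModelError(f"no compartment named {name!r}") from None

    @property
    def source(self) -> Compartment | None:
        for c in self.compartments:
            if c.role == "source":
                return c
        return None

    @property
    def finite_boxes(self) -> list[str]:
        return [c.name for c in self.compartments if c.finite]

    def influxes(self, box: str) -> list[FluxSpec]:
        return [f for f in self.fluxes if f.target == box]

    def effluxes(self, box: str) -> list[FluxSpec]:
        return [f for f in self.fluxes if f.source == box]

    def flux(self, source: str, target: str) -> FluxSpec:
        for f in self.fluxes:
            if f.edge == (source, target):
                return f
        raise ModelError(f"no flux {source}->{target}")

    # -- derived structures ----------------------------------------------

    def with_fluxes(self, replacements: Mapping[tuple[str, str], FluxSpec]) -> "BoxModel":
        """A copy with some flux edges replaced (keyed by (source, target))."""
        new = [replacements.get(f.edge, f) for f in self.fluxes]
        extra = [v for k, v in replacements.items() if k not in {f.edge for f in self.fluxes}]
        return BoxModel(self.compartments, new + list(extra), self.name, self.description)

    def linear_system(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
        """Rate matrix and forcing of the delta-dynamics over finite boxes.

        Returns ``(A, b_const, b_source, boxes)`` such that

            d(delta)/dt = A @ delta + b_const + b_source * diet_delta(t)

        ``b_const`` collects the per-mil fractionation offsets, ``b_source``
        the coupling to the (single) source composition.
        """
        boxes = self.finite_boxes
        idx = {b: i for i, b in enumerate(boxes)}
        n = len(boxes)
        A = np.zeros((n, n))
        b_const = np.zeros(n)
        b_source = np.zeros(n)
        mass = {b: self._by_name[b].mass for b in boxes}
        for f in self.fluxes:
            if f.target in idx:
                i = idx[f.target]
                if f.source in idx:
                    A[i, idx[f.source]] += f.rate / mass[f.target]
                elif self._by_name[f.source].role == "source":
                    b_source[i] += f.rate / mass[f.target]
                b_const[i] += f.rate * f.cap_delta / mass[f.target]
            if f.source in idx:
                j = idx[f.source]
                A[j, j] -= f.rate / mass[f.source]
                b_const[j] -= f.rate * f.cap_delta / mass[f.source]
        return A, b_const, b_source, boxes


# -- operations ----------------------------------------------------------


def validate_mass_balance(model: BoxModel, tolerance: float = BALANCE_TOL) -> BalanceReport:
    """Per-compartment (influx - efflux) report over finite boxes, ug/day."""
    imbalance = {}
    for box in model.finite_boxes:
        inflow = sum(f.rate for f in model.influxes(box))
        outflow = sum(f.rate for f in model.effluxes(box))
        imbalance[box] = inflow - outflow
    return BalanceReport(imbalance, tolerance)


def steady_state(model: BoxModel, diet_delta: float, method: str = "delta") -> SteadyState:
    """Analytic steady-state delta66Zn of every finite box.

    ``method="delta"`` solves the exactly linear delta-notation balance;
    ``method="ratio"`` solves the ratio bookkeeping (fluxes carry
    ``ratio_source * alpha``) and converts back — a cross-check that differs
    from the default by O(Delta^2/10^6).
    """
    A, b_const, b_source, boxes = model.linear_system()
    _check_nonsingular(model, A, boxes)
    if method == "delta":
        rhs = -(b_const + b_source * diet_delta)
        sol = np.linalg.solve(A, rhs)
        return SteadyState(dict(zip(boxes, sol)), diet_delta)
    if method == "ratio":
        return _steady_state_ratio(model, diet_delta, boxes)
    raise ValueError(f"unknown method {method!r}")


def _check_nonsingular(model: BoxModel, A: np.ndarray, boxes: list[str]) -> None:
    for i, box in enumerate(boxes):
        if A[i, i] == 0.0:
            raise ModelError(f"singular system: finite box {box!r} has zero efflux")
    if abs(np.linalg.det(A)) < 1e-300:
        raise ModelError("singular system: model is disconnected or degenerate")


def _steady_state_ratio(model: BoxModel, diet_delta: float, boxes: list[str]) -> SteadyState:
    # linear in the isotope ratio r: sum_in F r_src alpha = r_box sum_out F alpha
    idx = {b: i for i, b in enumerate(boxes)}
    n = len(boxes)
    M = np.zeros((n, n))
    rhs = np.zeros(n)
    r_diet = 1.0 + diet_delta / 1000.0  # ratios normalised to the standard
    for f in model.fluxes:
        if f.target in idx:
            i = idx[f.target]
            if f.source in idx:
                M[i, idx[f.source]] += f.rate * f.alpha
            elif model.compartment(f.source).role == "source":
                rhs[i] -= f.rate * f.alpha * r_diet
        if f.source in idx:
            j = idx[f.source]
            M[j, j] -= f.rate * f.alpha
    sol = np.linalg.solve(M, rhs)
    return SteadyState({b: (sol[idx[b]] - 1.0) * 1000.0 for b in boxes}, diet_delta)


def residence_time(model: BoxModel, box: str) -> float:
    """Mean residence time of a finite box: mass / total efflux, days.

    Reported in the literature under a ``t_1/2`` label, but defined here
    without a ln 2 factor — mass over efflux is the mean time a Zn atom
    spends in the pool and is the definition that reproduces the published
    rat turnover table (e.g. muscle 1960/227 = 8.6 d).
    """
    comp = model.compartment(box)
    if not comp.finite:
        raise ModelError(f"residence time undefined for infinite box {box!r}")
    efflux = sum(f.rate for f in model.effluxes(box))
    if efflux <= 0:
        raise ModelError(f"dead-end finite box {box!r}: zero efflux")
    return comp.mass / efflux


def relaxation_modes(model: BoxModel) -> list[RelaxationMode]:
    """Eigenmodes of the delta-dynamics, slowest last, with dominant boxes.

    Relaxation times are -1/eigenvalue of the rate matrix over finite
    evolving boxes (source held fixed, sinks excluded).  They characterise
    the whole system, not single reservoirs; each mode is tagged with the
    box carrying the largest eigenvector weight.
    """
    A, _, _, boxes = model.linear_system()
    _check_nonsingular(model, A, boxes)
    eigvals, eigvecs = np.linalg.eig(A)
    modes = []
    for k in range(len(eigvals)):
        lam = eigvals[k].real
        if lam >= 0:
            dom = boxes[int(np.argmax(np.abs(eigvecs[:, k])))]
            raise ModelError(
                f"system not dissipative: eigenvalue {lam:.3g} >= 0 (dominant box {dom!r})"
            )
        dom = boxes[int(np.argmax(np.abs(eigvecs[:, k])))]
        modes.append(RelaxationMode(time=-1.0 / lam, dominant_box=dom))
    modes.sort(key=lambda m: m.time)
    return modes


def relaxation_times(model: BoxModel) -> np.ndarray:
    """Sorted (ascending) whole-system relaxation times in days."""
    return np.array([m.time for m in relaxation_modes(model)])


# -- config round-trip ---------------------------------------------------


def model_to_dict(model: BoxModel) -> dict:
    return {
        "name": model.name,
        "description": model.description,
        "compartments": [
            {
                "name": c.name,
                "mass": "infinite" if c.infinite else c.mass,
                "role": c.role,
                **({"delta0": c.delta0} if c.delta0 is not None else {}),
            }
            for c in model.compartments
        ],
        "fluxes": [
            {"from": f.source, "to": f.target, "rate": f.rate, "alpha": f.alpha}
            for f in model.fluxes
        ],
    }


def model_from_dict(doc: dict) -> BoxModel:
    comps = []
    for c in doc.get("compartments", []):
        mass = c.get("mass")
        if isinstance(mass, str):
            if mass.lower() != "infinite":
                raise ModelError(f"bad mass {mass!r} for box {c.get('name')!r}")
            mass = None
        comps.append(
            Compartment(
                name=c["name"],
                mass=mass,
                role=c.get("role", "internal"),
                delta0=c.get("delta0"),
            )
        )
    fluxes = []
    for f in doc.get("fluxes", []):
        alpha = f.get("alpha")
        if alpha is None and "cap_delta" in f:
            alpha = delta_to_alpha(f["cap_delta"])
        spec = FluxSpec(source=f["from"], target=f["to"], rate=f["rate"], alpha=alpha or 1.0)
        if "cap_delta" in f and abs(spec.cap_delta - f["cap_delta"]) > 0.005:
            raise ModelError(
                f"inconsistent alpha/cap_delta on flux {f['from']}->{f['to']}: "
                f"{spec.cap_delta:.4f} vs {f['cap_delta']}"
            )
        fluxes.append(spec)
    return BoxModel(comps, fluxes, doc.get("name", "model"), doc.get("description", ""))


def load_model(path: str | Path) -> BoxModel:
    """Read a model config (YAML or JSON) and validate it."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ModelError(f"config {path} is not a mapping")
    return model_from_dict(doc)


def save_model(model: BoxModel, path: str | Path) -> None:
    path = Path(path)
    doc = model_to_dict(model)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
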