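"""Synthetic observation generator.

Everything the pipeline consumes can be produced here without downloads:
noisy steady-state observation tables from a known generating model,
diet-switch time series for the turnover calibration, and random small
balanced models for property tests.

The noise model is independent Gaussian per replicate per compartment
(measured tables report only 2SE-based confidence intervals, so no
covariance structure is available to emulate).  Reported half-widths are
2 SE = 2 sd / sqrt(n), matching how the measured table defines them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import DietForcing, simulate
from .model import BoxModel, Compartment, FluxSpec, delta_to_alpha, steady_state
from .observations import Observation, ObservationTable

__all__ = [
    "DEFAULT_GROUP_DIETS",
    "SyntheticSpec",
    "rat_synthetic_spec",
    "generate_observations",
    "generate_switch_series",
    "random_model",
]

#: Default dietary delta66Zn (per mil) per feeding group.  The reference
#: (supplier) value is measured; the alternatives follow the qualitative
#: ordering of the feeding experiments — lucerne lowest, then the
#: animal-based feeds, supplier's and the vegetable mix highest — spanning
#: roughly -0.3 to 1.0 per mil.  Measured values exist only for the
#: animal-meal (-0.09) and bone-addition (0.00) feeds.
DEFAULT_GROUP_DIETS: dict[str, float] = {
    "supplier": 0.42,
    "lucerne": -0.30,
    "animal_meal": -0.09,
    "insect_meal": -0.05,
    "bone_addition": 0.00,
    "day_old_chick": 0.10,
    "vegetable_mix": 0.50,
}


@dataclass
class SyntheticSpec:
    """Conditions for a synthetic feeding experiment.

    ``noise_sd`` is the per-replicate measurement SD per compartment;
    ``replicates`` the per-compartment sample count (small groups, 1-6
    animals).  ``between_individual_sd`` adds an optional animal-level
    random effect on top of measurement noise (default off: no measured
    estimate of it exists separately from growth effects).
    """

    model: BoxModel
    diet_deltas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUP_DIETS))
    reference_group: str = "supplier"
    noise_sd: dict[str, float] = field(default_factory=dict)
    replicates: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    switch_day: float = 0.0
    sampling_days: tuple[float, ...] = (54.0,)
    experiment_days: float = 54.0
    between_individual_sd: float = 0.0

    def __post_init__(self) -> None:
        for box, sd in self.noise_sd.items():
            if sd <= 0:
                raise ValueError(f"noise sd for {box!r} must be > 0, got {sd}")
        for box, n in self.replicates.items():
            if n < 1:
                raise ValueError(f"replicate count for {box!r} must be >= 1, got {n}")
        if any(d > self.experiment_days for d in self.sampling_days):
            raise ValueError("sampling day beyond the experiment length")
        if self.reference_group not in self.diet_deltas:
            raise ValueError(f"unknown reference group {self.reference_group!r}")

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)


def rat_synthetic_spec(seed: int = 0, model: BoxModel | None = None) -> SyntheticSpec:
    """Study-condition defaults for the rat experiment.

    Noise SDs are half the observed confidence half-widths (CI = 2SE) of
    the measured table; replicate counts mirror the small per-group sample
    sizes (single animals for plasma and integument, up to five feed
    aliquots).
    """
    from .rat import rat_model, rat_observations

    if model is None:
        model = rat_model("fitted_final")
    obs = rat_observations()
    noise_sd = {o.compartment: o.ci_halfwidth / 2.0 for o in obs}
    replicates = {o.compartment: o.n for o in obs}
    return SyntheticSpec(
        model=model,
        noise_sd=noise_sd,
        replicates=replicates,
        seed=seed,
        experiment_days=54.0,
        sampling_days=(54.0,),
    )


def generate_observations(
    spec: SyntheticSpec, group: str | None = None
) -> tuple[ObservationTable, dict[str, float]]:
    """Noisy steady-state observation table plus the generating truth.

    Each compartment's observed value is the mean of ``n`` Gaussian
    replicates around the true steady state of the generating model under
    the group's diet; the reported half-width is 2 SE.  Deterministic for a
    fixed seed.
    """
    group = group or spec.reference_group
    diet = spec.diet_deltas[group]
    rng = np.random.default_rng(spec.seed)
    ss = steady_state(spec.model, diet)
    source = spec.model.source
    truth: dict[str, float] = {b: ss[b] for b in spec.model.finite_boxes}
    if source is not None:
        truth[source.name] = diet
    rows = []
    for box, sd in spec.noise_sd.items():
        if box not in truth:
            continue
        n = spec.replicates.get(box, 1)
        center = truth[box]
        if spec.between_individual_sd > 0:
            center = center + rng.normal(0.0, spec.between_individual_sd)
        reps = rng.normal(center, sd, size=n)
        rows.append(
            Observation(
                compartment=box,
                delta=float(reps.mean()),
                ci_halfwidth=2.0 * sd / np.sqrt(n),
                n=n,
            )
        )
    return ObservationTable(rows), truth


def generate_switch_series(
    spec: SyntheticSpec,
    boxes: list[str],
    group: str = "lucerne",
    dt: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noisy observations of selected boxes through a diet switch.

    The organism starts at steady state with the reference diet and is
    switched at ``spec.switch_day`` to the group's diet; the listed boxes
    are sampled at ``spec.sampling_days``.  Returns the observation-at-time
    table (columns ``day, compartment, delta66Zn, ci_halfwidth, n``) and
    the noiseless truth.
    """
    if spec.switch_day < 0:
        raise ValueError("switch day must be >= 0")
    if any(d < spec.switch_day for d in spec.sampling_days):
        raise ValueError("sampling before the switch needs a pre-switch steady state "
                         "(set switch_day <= min(sampling_days))")
    rng = np.random.default_rng(spec.seed)
    forcing = DietForcing.step(
        before=spec.diet_deltas[spec.reference_group],
        after=spec.diet_deltas[group],
        switch_day=spec.switch_day,
    )
    t_end = max(max(spec.sampling_days), dt)
    traj = simulate(spec.model, forcing, t_end=t_end + dt, dt=dt)
    obs_rows = []
    truth_rows = []
    for box in boxes:
        sd = spec.noise_sd.get(box)
        if sd is None:
            raise ValueError(f"no noise sd specified for {box!r}")
        n = spec.replicates.get(box, 1)
        for day in spec.sampling_days:
            true = float(np.interp(day, traj.t, traj[box]))
            reps = rng.normal(true, sd, size=n)
            obs_rows.append(
                {
                    "day": day,
                    "compartment": box,
                    "delta66Zn": float(reps.mean()),
                    "ci_halfwidth": 2.0 * sd / np.sqrt(n),
                    "n": n,
                }
            )
            truth_rows.append({"day": day, "compartment": box, "delta66Zn": true})
    return pd.DataFrame(obs_rows), pd.DataFrame(truth_rows)


def random_model(
    rng: np.random.Generator,
    n_boxes: int = 4,
    max_delta: float = 0.5,
) -> BoxModel:
    """A random small balanced box model for property tests.

    Built balanced by construction: a through-flow chain from the source
    across every box to a sink, plus random symmetric exchange pairs
    between non-adjacent boxes (equal forward and backward rates preserve
    balance; adjacent pairs already carry the chain edge).
    Fractionation amplitudes are drawn within ``+-max_delta`` per mil.
    """
    if not 1 <= n_boxes <= 8:
        raise ValueError("n_boxes must be in [1, 8]")
    names = [f"box{i}" for i in range(n_boxes)]
    comps = [Compartment("diet", role="source", delta0=0.0)]
    for b in names:
        comps.append(Compartment(b, mass=float(rng.uniform(10.0, 1000.0))))
    comps.append(Compartment("waste", role="sink"))

    def amp() -> float:
        return float(rng.uniform(-max_delta, max_delta))

    through = float(rng.uniform(50.0, 500.0))
    chain = ["diet"] + names + ["waste"]
    fluxes = [
        FluxSpec(a, b, through, delta_to_alpha(amp()))
        for a, b in zip(chain[:-1], chain[1:])
    ]
    # random symmetric exchange pairs between non-adjacent boxes (adjacent
    # pairs already carry the chain edge; one edge per ordered pair)
    for i in range(n_boxes):
        for j in range(i + 2, n_boxes):
            if rng.random() < 0.5:
                rate = float(rng.uniform(1.0, 300.0))
                fluxes.append(FluxSpec(names[i], names[j], rate, delta_to_alpha(amp())))
                fluxes.append(FluxSpec(names[j], names[i], rate, delta_to_alpha(amp())))
    return BoxModel(comps, fluxes, name="random")
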