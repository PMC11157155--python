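"""The whole-body Zn cycle of a 370 g laboratory rat, shipped as data.

Three variants of the flux configuration are bundled:

``printed``
    The literature flux table verbatim.  Its muscle-to-plasma return flux
    (900 ug/day) does not balance the network: plasma gains and muscle
    loses 673 ug/day.  Kept for provenance; fails mass balance by design.
``balanced``
    Muscle-to-plasma set to 227 ug/day (equal to plasma-to-muscle), which
    balances every box exactly and matches the published muscle mean
    residence time 1960/227 = 8.6 days.
``fitted_final``
    The balanced network with the calibrated unknowns: bone exchange
    3212/300.2 ~ 10.70 ug/day each way (bone mean residence 300.2 days,
    from the diet-switch calibration), plasma-to-integument loss 4 ug/day
    (low integument loss / high endogenous loss), renal fractionation
    alpha_KDN-UR = 1.00044, and the intestinal-absorption and integument
    fractionation amplitudes from this package's own sweep fit against the
    observed compositions.

Compartment masses (ug) and the observed delta66Zn table (per mil vs
JMC-Lyon, half-widths = 2SE) come from the supplier-diet reference group
assumed at diet-body isotope equilibrium.  Kidney is measured but flagged
``excluded``: it acts as an interface and is not fitted.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .model import BoxModel, load_model
from .observations import ObservationTable, load_observations

__all__ = [
    "RAT_VARIANTS",
    "DIET_DELTA",
    "BONE_RESIDENCE_DAYS",
    "rat_model",
    "rat_observations",
    "rat_sweep_axes",
    "data_path",
]

RAT_VARIANTS = ("printed", "balanced", "fitted_final")

#: delta66Zn of the supplier feed, per mil (the reference diet)
DIET_DELTA = 0.42

#: calibrated mean residence time of Zn in rat bone, days
BONE_RESIDENCE_DAYS = 300.2

#: bone mass (ug) / residence -> exchange flux each way, ug/day
BONE_EXCHANGE_FLUX = 3212 / BONE_RESIDENCE_DAYS


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(resources.files("znbox.data") / name)


def rat_model(variant: str = "fitted_final") -> BoxModel:
    """Load a bundled rat Zn model variant.

    Parameters
    ----------
    variant : {"printed", "balanced", "fitted_final"}
    """
    if variant not in RAT_VARIANTS:
        raise ValueError(f"unknown rat model variant {variant!r}; choose from {RAT_VARIANTS}")
    return load_model(data_path(f"rat_zn_{variant}.yaml"))


def rat_sweep_axes():
    """The default 5-axis battery over the rat model's unknown parameters.

    Axes (declared order fixes the grid's row-major node ordering):

    1. intestinal absorption amplitude, split between intestine->plasma and
       plasma->intestine at opposite signs, -0.30 to +0.30 per mil in
       0.025 per mil steps (the plasma steady state moves ~1.9 per mil per
       per-mil of this amplitude, so it needs the finest resolution);
    2. integument-transport amplitude on plasma->integument, -0.50 to 0 per
       mil in 0.05 steps;
    3. urinary-loss amplitude on kidney->urine, 0 to 1 per mil in 0.1 steps
       (weak leverage: the urine flux is 7/1000 of intake);
    4. plasma<->bone exchange, both directions together, 1.1 to 231.1
       ug/day, 15 log-spaced points (bone residence 3212/flux days);
    5. plasma->integument loss, 4 to 180 ug/day, 15 log-spaced points,
       compensated through the endogenous loss to the intestine and the
       fecal through-flux so every box stays balanced.
    """
    from .sweep import FluxAxis, FractionationAxis

    return [
        FractionationAxis(
            "int_absorption_amplitude",
            edge=("intestine", "plasma"),
            paired_edge=("plasma", "intestine"),
            lo=-0.30,
            hi=0.30,
            n_points=25,
        ),
        FractionationAxis(
            "integument_amplitude", edge=("plasma", "integument"), lo=-0.50, hi=0.0, n_points=11
        ),
        FractionationAxis(
            "urinary_amplitude", edge=("kidney", "urine"), lo=0.0, hi=1.0, n_points=11
        ),
        FluxAxis(
            "bone_exchange",
            edges=(("plasma", "bone"), ("bone", "plasma")),
            lo=1.1,
            hi=231.1,
            n_points=15,
            scale="log",
        ),
        FluxAxis(
            "integument_flux",
            edges=(("plasma", "integument"), ("integument", "waste")),
            compensate=(
                ("plasma", "intestine"),
                ("intestine", "feces"),
                ("feces", "waste"),
            ),
            lo=4.0,
            hi=180.0,
            n_points=15,
            scale="log",
        ),
    ]


def rat_observations() -> ObservationTable:
    """The observed per-compartment delta66Zn table for supplier-fed rats.

    Eight constrained compositions (diet, plasma, liver, RBC, muscle, bone,
    integument, feces) plus kidney flagged excluded from fitting.  Intestine
    and urine were not measured and carry no row.
    """
    return load_observations(data_path("rat_observations.csv"))
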