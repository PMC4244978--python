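"""Packaged example networks: the A⇄B⇄C toy system and three TCA-cycle variants.

The TCA fixtures cover the eight-reaction oxidative cycle (citrate synthase
through malate dehydrogenase) with chemostatted cofactors, in three
ecological flavors:

``ecoli``
    Heterotrophic cycle; NAD+/NADH, Q/QH2 and substrate-level ATP synthesis
    at succinyl-CoA synthetase; cofactor clamps drive the cycle in the
    oxidative (citrate → oxaloacetate) direction.
``cyano``
    Cyanobacterial variant: the 2-oxoglutarate → succinate segment uses a
    ferredoxin redox pair instead of the NAD+/ADP couple, so high ATP does
    not retard the cycle; ADP/ATP/Pi are absent from the network.
``chlorobium``
    Green-sulfur-bacterium variant: cofactor clamp potentials reverse the
    driving force, so the cycle runs reductively (oxaloacetate → citrate),
    fixing CO2.

All numerical potentials are SYNTHETIC fixture values chosen for qualitative
fidelity (direction of driving; citrate and succinyl-CoA lowest among the
intermediates so that small pools condense onto them).  They are tagged as
such in every file header and are not measurements.
"""

from __future__ import annotations

from .network import (
    CLAMPED,
    DYNAMIC,
    NetworkError,
    Reaction,
    ReactionNetwork,
    Species,
    ThermoContext,
    parse_equation,
)
from .thermo import SystemState

SYNTHETIC_TAG = "SYNTHETIC fixture potentials: qualitative, not measured values"

#: Default mapping of particle counts to concentration: 1 particle ≙ 1 μM.
PARTICLES_PER_UM = 1.0

#: Initial intermediate level, ~20 μM each at the default volume scale.
INTERMEDIATE_UM = 20.0

TCA_INTERMEDIATES = (
    "citrate",
    "isocitrate",
    "oxoglutarate",
    "succinyl_CoA",
    "succinate",
    "fumarate",
    "malate",
    "oxaloacetate",
)

# Reduced potentials mu_hat = mu0/RT (dimensionless, SYNTHETIC).
_INTERMEDIATE_MU_HAT = {
    "citrate": -1.5,
    "isocitrate": 0.5,
    "oxoglutarate": 0.0,
    "succinyl_CoA": -1.5,
    "succinate": -0.3,
    "fumarate": 0.0,
    "malate": -0.2,
    "oxaloacetate": 1.0,
}

_COFACTOR_MU_HAT = {
    "ecoli": {
        "AcCoA": 5.0, "CoA": 0.0, "NAD": 1.0, "NADH": -1.0,
        "ADP": 0.5, "ATP": 0.5, "Pi": 0.0, "Q": 1.0, "QH2": -1.0,
        "CO2": -2.0, "H2O": 0.0,
    },
    "cyano": {
        "AcCoA": 5.0, "CoA": 0.0, "NAD": 1.0, "NADH": -1.0,
        "Fdox": 2.0, "Fdred": -2.0, "Q": 1.0, "QH2": -1.0,
        "CO2": -2.0, "H2O": 0.0,
    },
    "chlorobium": {
        "AcCoA": -4.0, "CoA": 0.0, "NAD": -1.0, "NADH": 1.5,
        "ADP": 0.5, "ATP": 0.5, "Pi": 0.0, "Q": -1.0, "QH2": 1.0,
        "CO2": 2.5, "H2O": 0.0,
    },
}

_COMMON_REACTIONS = {
    "citrate_synthase": "AcCoA + oxaloacetate + H2O -> citrate + CoA",
    "aconitase": "citrate -> isocitrate",
    "isocitrate_dehydrogenase": "isocitrate + NAD -> oxoglutarate + CO2 + NADH",
    "succinate_dehydrogenase": "succinate + Q -> fumarate + QH2",
    "fumarase": "fumarate + H2O -> malate",
    "malate_dehydrogenase": "malate + NAD -> oxaloacetate + NADH",
}

_VARIANT_REACTIONS = {
    "ecoli": {
        **_COMMON_REACTIONS,
        "oxoglutarate_dehydrogenase":
            "oxoglutarate + NAD + CoA -> succinyl_CoA + CO2 + NADH",
        "succinyl_CoA_synthetase":
            "succinyl_CoA + ADP + Pi -> succinate + ATP + CoA",
    },
    "cyano": {
        **_COMMON_REACTIONS,
        "oxoglutarate_dehydrogenase":
            "oxoglutarate + Fdox + CoA -> succinyl_CoA + CO2 + Fdred",
        "succinyl_CoA_synthetase": "succinyl_CoA -> succinate + CoA",
    },
    "chlorobium": {
        **_COMMON_REACTIONS,
        "oxoglutarate_dehydrogenase":
            "oxoglutarate + NAD + CoA -> succinyl_CoA + CO2 + NADH",
        "succinyl_CoA_synthetase":
            "succinyl_CoA + ADP + Pi -> succinate + ATP + CoA",
    },
}

#: Oxidative traversal order of the cycle (citrate synthase onward).
TCA_CYCLE_ORDER = (
    "citrate_synthase",
    "aconitase",
    "isocitrate_dehydrogenase",
    "oxoglutarate_dehydrogenase",
    "succinyl_CoA_synthetase",
    "succinate_dehydrogenase",
    "fumarase",
    "malate_dehydrogenase",
)

DEFAULT_CLAMP_COUNT = 100


def make_abc_fixture(
    mu_hat: tuple[float, float, float] = (0.0, 0.0, 0.0),
    n_total: int = 6,
    temperature: float = 298.15,
) -> tuple[ReactionNetwork, SystemState]:
    """Closed three-species chain A⇄B⇄C with the given reduced potentials.

    The initial state spreads ``n_total`` particles as evenly as possible
    (remainder to the earlier species).
    """
    if n_total < 0:
        raise NetworkError("n_total must be >= 0")
    ctx = ThermoContext(temperature)
    kbt = ctx.kBT_kJ_per_mol
    species = [
        Species(id=sid, mu0=m * kbt, mu_hat=m, role=DYNAMIC)
        for sid, m in zip(("A", "B", "C"), mu_hat)
    ]
    reactions = [
        Reaction(id="AB", reactants={"A": 1}, products={"B": 1}),
        Reaction(id="BC", reactants={"B": 1}, products={"C": 1}),
    ]
    net = ReactionNetwork(context=ctx, species=species, reactions=reactions)
    base, rem = divmod(n_total, 3)
    counts = {
        sid: base + (1 if k < rem else 0)
        for k, sid in enumerate(("A", "B", "C"))
    }
    return net, SystemState.from_counts(net, counts)


def make_tca_fixture(
    variant: str = "ecoli",
    pool_scale: float = 1.0,
    temperature: float = 298.15,
    particles_per_uM: float = PARTICLES_PER_UM,
    clamp_count: int = DEFAULT_CLAMP_COUNT,
) -> tuple[ReactionNetwork, SystemState]:
    """Eight-reaction TCA cycle over eight dynamic intermediates.

    Intermediates are initialized uniformly at
    ``round(20 μM × particles_per_uM × pool_scale)`` particles each; the
    cofactors are clamped species.  ``pool_scale`` scales the intermediate
    pool without touching the boundary conditions.
    """
    if variant not in _VARIANT_REACTIONS:
        raise NetworkError(
            f"unknown TCA variant {variant!r}; "
            f"expected one of {sorted(_VARIANT_REACTIONS)}"
        )
    if pool_scale <= 0:
        raise NetworkError("pool_scale must be positive")
    ctx = ThermoContext(temperature)
    kbt = ctx.kBT_kJ_per_mol
    species = [
        Species(id=sid, mu0=_INTERMEDIATE_MU_HAT[sid] * kbt,
                mu_hat=_INTERMEDIATE_MU_HAT[sid], role=DYNAMIC)
        for sid in TCA_INTERMEDIATES
    ]
    for sid, m in _COFACTOR_MU_HAT[variant].items():
        species.append(
            Species(id=sid, mu0=m * kbt, mu_hat=m, role=CLAMPED,
                    clamp_count=clamp_count)
        )
    reactions = []
    for rid in TCA_CYCLE_ORDER:
        reactants, products = parse_equation(_VARIANT_REACTIONS[variant][rid])
        reactions.append(Reaction(id=rid, reactants=reactants, products=products))
    net = ReactionNetwork(context=ctx, species=species, reactions=reactions)
    per_species = int(round(INTERMEDIATE_UM * particles_per_uM * pool_scale))
    state = SystemState.from_counts(
        net, {sid: per_species for sid in TCA_INTERMEDIATES}
    )
    return net, state


FIXTURE_NAMES = ("abc", "tca_ecoli", "tca_cyano", "tca_chlorobium")


def make_fixture(name: str, **params) -> tuple[ReactionNetwork, SystemState]:
    """Dispatch on a fixture name (``abc`` or ``tca_<variant>``)."""
    if name == "abc":
        return make_abc_fixture(**params)
    if name.startswith("tca_"):
        return make_tca_fixture(variant=name[4:], **params)
    raise NetworkError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
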