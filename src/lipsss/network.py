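"""Carbon-transition network for TCA-cycle isotope labeling.

The network is configuration data: metabolite pools (2-6 carbons each), atom
transitions between them, and the timed label-infusion schedule.  The default
network describes acetate-fed cardiac TCA metabolism: labeled acetate enters
via acetyl-CoA (with a mono-exponential transport delay ``t_trans`` and an
unlabeled dilution fraction ``p_dil``), turns through citrate, alpha-
ketoglutarate, succinate and oxaloacetate, exchanges with the glutamate and
aspartate amino-acid pools, and is replenished by an anaplerotic inflow at
succinate balanced by an efflux at oxaloacetate.

Carbon/bit convention: carbon ``i`` of a pool corresponds to bit ``i - 1``
(least-significant bit first) of its isotopomer index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "CO2",
    "EFFLUX",
    "ROLE_TCA",
    "ROLE_EXCHANGE",
    "ROLE_ANAPLEROSIS_IN",
    "ROLE_ANAPLEROSIS_OUT",
    "ROLE_INPUT",
    "PARAM_ORDER",
    "ConfigError",
    "ModelParameters",
    "PoolSpec",
    "AtomTransition",
    "Phase",
    "LabelSchedule",
    "NetworkConfig",
    "default_pools",
    "default_transitions",
    "default_config",
    "load_config",
    "dump_config",
]

#: sink labels usable as atom-map destinations
CO2 = "CO2"
EFFLUX = "EFFLUX"
_SINKS = (CO2, EFFLUX)

ROLE_TCA = "TCA"
ROLE_EXCHANGE = "EXCHANGE"
ROLE_ANAPLEROSIS_IN = "ANAPLEROSIS_IN"
ROLE_ANAPLEROSIS_OUT = "ANAPLEROSIS_OUT"
ROLE_INPUT = "INPUT"

_ROLES = (ROLE_TCA, ROLE_EXCHANGE, ROLE_ANAPLEROSIS_IN, ROLE_ANAPLEROSIS_OUT, ROLE_INPUT)

#: canonical ordering of the five flux parameters
PARAM_ORDER = ("j_tca", "j_exch", "t_trans", "p_dil", "p_anap")

#: acetyl-CoA isotopomer index per infused acetate species
#: (C1 = carboxyl = bit 0, C2 = methyl = bit 1)
ACETYL_ISOTOPOMER = {
    "unlabeled": 0,
    "acetate_2_13c": 0b10,   # methyl carbon labeled
    "acetate_1_2_13c": 0b11,  # both carbons labeled
}


class ConfigError(ValueError):
    """Raised for inconsistent model configuration."""


@dataclass(frozen=True)
class ModelParameters:
    """The five flux parameters of the model.

    Attributes
    ----------
    j_tca : float
        TCA cycle flux, umol min^-1 (g dry weight)^-1.
    j_exch : float
        Bidirectional amino-acid transamination exchange flux, same units.
    t_trans : float
        Time constant of label transport into acetyl-CoA, min.
    p_dil : float
        Fraction of acetyl-CoA from unlabeled endogenous substrates, in [0, 1].
    p_anap : float
        Anaplerotic inflow relative to ``j_tca`` (dimensionless, >= 0).
    """

    j_tca: float
    j_exch: float
    t_trans: float
    p_dil: float
    p_anap: float

    def __post_init__(self):
        vals = (self.j_tca, self.j_exch, self.t_trans, self.p_dil, self.p_anap)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite model parameters: {vals}")
        if self.j_tca < 0:
            raise ValueError(f"j_tca must be >= 0, got {self.j_tca}")
        if self.j_exch < 0:
            raise ValueError(f"j_exch must be >= 0, got {self.j_exch}")
        if self.t_trans <= 0:
            raise ValueError(f"t_trans must be > 0, got {self.t_trans}")
        if not 0.0 <= self.p_dil <= 1.0:
            raise ValueError(f"p_dil must be in [0, 1], got {self.p_dil}")
        if self.p_anap < 0:
            raise ValueError(f"p_anap must be >= 0, got {self.p_anap}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_ORDER], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "ModelParameters":
        return cls(**{k: float(v) for k, v in zip(PARAM_ORDER, arr, strict=True)})

    def replace(self, **kwargs) -> "ModelParameters":
        return _dc_replace(self, **kwargs)


@dataclass(frozen=True)
class PoolSpec:
    """A metabolite pool.

    ``dynamic`` pools carry isotopomer state variables; non-dynamic pools are
    forcings (infused acetate, the unlabeled dilution pool, the anaplerotic
    source) whose composition is imposed, not integrated.
    """

    name: str
    n_carbons: int
    concentration: float | None = None  # umol / g dry weight
    dynamic: bool = True

    def __post_init__(self):
        if self.n_carbons < 1:
            raise ConfigError(f"pool {self.name!r}: n_carbons must be >= 1")
        if self.dynamic and (self.concentration is None or self.concentration <= 0):
            raise ConfigError(
                f"pool {self.name!r}: dynamic pools need a positive concentration"
            )

    @property
    def n_isotopomers(self) -> int:
        return 1 << self.n_carbons


@dataclass(frozen=True)
class AtomTransition:
    """A carbon-atom transition between pools.

    ``atom_map`` is a tuple of ``((src_pool, src_carbon), (dst, dst_carbon))``
    pairs; ``dst`` may be a pool name or one of the sinks ``CO2``/``EFFLUX``.
    ``weight`` is the fraction of the role's flux this transition carries
    (e.g. 0.5 for each branch of the symmetric alpha-ketoglutarate to
    succinate step).
    """

    name: str
    sources: tuple[str, ...]
    targets: tuple[str, ...]
    atom_map: tuple[tuple[tuple[str, int], tuple[str, int]], ...]
    role: str
    weight: float = 1.0

    def __post_init__(self):
        if self.role not in _ROLES:
            raise ConfigError(f"transition {self.name!r}: unknown role {self.role!r}")
        if not 0 < self.weight <= 1:
            raise ConfigError(f"transition {self.name!r}: weight must be in (0, 1]")


@dataclass(frozen=True)
class Phase:
    """One contiguous infusion phase with a fixed acetate composition."""

    t_start: float
    t_end: float
    composition: tuple[tuple[str, float], ...]

    def __post_init__(self):
        if not self.t_end > self.t_start:
            raise ConfigError(f"phase [{self.t_start}, {self.t_end}] is empty")
        comp = dict(self.composition)
        unknown = set(comp) - set(ACETYL_ISOTOPOMER)
        if unknown:
            raise ConfigError(f"unknown acetate species {sorted(unknown)}")
        if abs(sum(comp.values()) - 1.0) > 1e-9:
            raise ConfigError(f"phase composition must sum to 1, got {comp}")
        if any(v < 0 for v in comp.values()):
            raise ConfigError("phase composition fractions must be >= 0")


@dataclass(frozen=True)
class LabelSchedule:
    """Ordered, contiguous infusion phases."""

    phases: tuple[Phase, ...]

    def __post_init__(self):
        if not self.phases:
            raise ConfigError("schedule needs at least one phase")
        for a, b in zip(self.phases, self.phases[1:]):
            if abs(a.t_end - b.t_start) > 1e-12:
                raise ConfigError(
                    f"phases must be contiguous: {a.t_end} != {b.t_start}"
                )

    @property
    def t_start(self) -> float:
        return self.phases[0].t_start

    @property
    def t_end(self) -> float:
        return self.phases[-1].t_end

    def composition_at(self, t: float) -> dict[str, float]:
        """Acetate isotopomer composition at time ``t``.

        Before the schedule starts the infusate is unlabeled; after the last
        phase the final composition is held (metabolism is normally arrested
        at the sampling time anyway).
        """
        if t < self.t_start:
            return {"unlabeled": 1.0}
        for ph in self.phases:
            if t < ph.t_end:
                return dict(ph.composition)
        return dict(self.phases[-1].composition)

    @classmethod
    def default(cls) -> "LabelSchedule":
        """4 min of [2-13C] acetate followed by 1.5 min of [1,2-13C] acetate."""
        return cls(
            phases=(
                Phase(0.0, 4.0, (("acetate_2_13c", 1.0),)),
                Phase(4.0, 5.5, (("acetate_1_2_13c", 1.0),)),
            )
        )


# ---------------------------------------------------------------------------
# default network
# ---------------------------------------------------------------------------

#: Default pool concentrations (umol/gdw).  Glutamate is measured per sample
#: and must be overridden; the small intermediate pools are order-of-magnitude
#: placeholders from the cardiac literature and have little influence on the
#: simulated glutamate labeling (they equilibrate fast relative to glutamate).
DEFAULT_CONCENTRATIONS = {
    "acetyl_coa": 0.05,
    "citrate": 1.0,
    "akg": 0.5,
    "succinate": 0.5,
    "oaa": 0.1,
    "glutamate": 20.0,
    "aspartate": 5.0,
}


def default_pools() -> tuple[PoolSpec, ...]:
    c = DEFAULT_CONCENTRATIONS
    return (
        # forcings
        PoolSpec("acetate", 2, None, dynamic=False),
        PoolSpec("dilution", 2, None, dynamic=False),
        PoolSpec("anaplerotic", 4, None, dynamic=False),
        # dynamic pools (state order)
        PoolSpec("acetyl_coa", 2, c["acetyl_coa"]),
        PoolSpec("citrate", 6, c["citrate"]),
        PoolSpec("akg", 5, c["akg"]),
        PoolSpec("succinate", 4, c["succinate"]),
        PoolSpec("oaa", 4, c["oaa"]),
        PoolSpec("glutamate", 5, c["glutamate"]),
        PoolSpec("aspartate", 4, c["aspartate"]),
    )


def _amap(*pairs):
    return tuple(((sp, sc), (tp, tc)) for (sp, sc, tp, tc) in pairs)


def _identity(src: str, tgt: str, n: int):
    return _amap(*((src, i, tgt, i) for i in range(1, n + 1)))


def default_transitions() -> tuple[AtomTransition, ...]:
    """The canonical cardiac acetate carbon-transition set.

    Citrate carbons 1-4 derive from oxaloacetate 1-4, citrate 5/6 from the
    acetyl carboxyl/methyl carbon.  On the way to alpha-ketoglutarate the
    oxaloacetate-derived C4 leaves as CO2 and the acetyl methyl carbon ends up
    at alpha-KG C4 (hence [2-13C]acetate labels glutamate C4 first).  The
    alpha-KG to succinate step is symmetric and carries two weight-0.5 atom
    maps; succinate to oxaloacetate is an identity map (fumarate scrambling is
    subsumed by the single symmetric step).
    """
    t = []
    # label input (represented by the acetyl-CoA relaxation; kept for
    # completeness of the network description)
    t.append(AtomTransition(
        "acetate_to_acetyl_coa", ("acetate",), ("acetyl_coa",),
        _identity("acetate", "acetyl_coa", 2), ROLE_INPUT))
    t.append(AtomTransition(
        "dilution_to_acetyl_coa", ("dilution",), ("acetyl_coa",),
        _identity("dilution", "acetyl_coa", 2), ROLE_INPUT))
    # citrate synthase (condensation)
    t.append(AtomTransition(
        "citrate_synthase", ("oaa", "acetyl_coa"), ("citrate",),
        _amap(("oaa", 1, "citrate", 1), ("oaa", 2, "citrate", 2),
              ("oaa", 3, "citrate", 3), ("oaa", 4, "citrate", 4),
              ("acetyl_coa", 1, "citrate", 5), ("acetyl_coa", 2, "citrate", 6)),
        ROLE_TCA))
    # citrate -> alpha-ketoglutarate + CO2
    t.append(AtomTransition(
        "citrate_to_akg", ("citrate",), ("akg",),
        _amap(("citrate", 1, "akg", 1), ("citrate", 2, "akg", 2),
              ("citrate", 3, "akg", 3), ("citrate", 4, CO2, 1),
              ("citrate", 5, "akg", 5), ("citrate", 6, "akg", 4)),
        ROLE_TCA))
    # symmetric alpha-KG -> succinate (+ CO2), two equally weighted branches
    t.append(AtomTransition(
        "akg_to_succinate_a", ("akg",), ("succinate",),
        _amap(("akg", 1, CO2, 1), ("akg", 2, "succinate", 1),
              ("akg", 3, "succinate", 2), ("akg", 4, "succinate", 3),
              ("akg", 5, "succinate", 4)),
        ROLE_TCA, weight=0.5))
    t.append(AtomTransition(
        "akg_to_succinate_b", ("akg",), ("succinate",),
        _amap(("akg", 1, CO2, 1), ("akg", 2, "succinate", 4),
              ("akg", 3, "succinate", 3), ("akg", 4, "succinate", 2),
              ("akg", 5, "succinate", 1)),
        ROLE_TCA, weight=0.5))
    # succinate -> oxaloacetate: base TCA flux plus the anaplerotic carry
    t.append(AtomTransition(
        "succinate_to_oaa", ("succinate",), ("oaa",),
        _identity("succinate", "oaa", 4), ROLE_TCA))
    t.append(AtomTransition(
        "succinate_to_oaa_anap", ("succinate",), ("oaa",),
        _identity("succinate", "oaa", 4), ROLE_ANAPLEROSIS_IN))
    # anaplerotic inflow (unlabeled) at succinate, balancing efflux at OAA
    t.append(AtomTransition(
        "anaplerotic_inflow", ("anaplerotic",), ("succinate",),
        _identity("anaplerotic", "succinate", 4), ROLE_ANAPLEROSIS_IN))
    t.append(AtomTransition(
        "oaa_efflux", ("oaa",), (),
        _amap(*(("oaa", i, EFFLUX, i) for i in range(1, 5))),
        ROLE_ANAPLEROSIS_OUT))
    # transamination exchanges (identity atom maps, single parameter j_exch)
    t.append(AtomTransition(
        "akg_to_glutamate", ("akg",), ("glutamate",),
        _identity("akg", "glutamate", 5), ROLE_EXCHANGE))
    t.append(AtomTransition(
        "glutamate_to_akg", ("glutamate",), ("akg",),
        _identity("glutamate", "akg", 5), ROLE_EXCHANGE))
    t.append(AtomTransition(
        "oaa_to_aspartate", ("oaa",), ("aspartate",),
        _identity("oaa", "aspartate", 4), ROLE_EXCHANGE))
    t.append(AtomTransition(
        "aspartate_to_oaa", ("aspartate",), ("oaa",),
        _identity("aspartate", "oaa", 4), ROLE_EXCHANGE))
    return tuple(t)


@dataclass(frozen=True)
class NetworkConfig:
    """Pools + transitions + schedule: everything the model compiler needs."""

    pools: tuple[PoolSpec, ...] = field(default_factory=default_pools)
    transitions: tuple[AtomTransition, ...] = field(default_factory=default_transitions)
    schedule: LabelSchedule = field(default_factory=LabelSchedule.default)


def default_config() -> NetworkConfig:
    return NetworkConfig()


# ---------------------------------------------------------------------------
# YAML (de)serialization
# ---------------------------------------------------------------------------

def config_to_dict(cfg: NetworkConfig) -> dict:
    return {
        "pools": [
            {"name": p.name, "n_carbons": p.n_carbons,
             "concentration": p.concentration, "dynamic": p.dynamic}
            for p in cfg.pools
        ],
        "transitions": [
            {"name": t.name, "sources": list(t.sources), "targets": list(t.targets),
             "role": t.role, "weight": t.weight,
             "atom_map": [[list(src), list(dst)] for src, dst in t.atom_map]}
            for t in cfg.transitions
        ],
        "schedule": [
            {"t_start": ph.t_start, "t_end": ph.t_end,
             "composition": dict(ph.composition)}
            for ph in cfg.schedule.phases
        ],
    }


def config_from_dict(d: Mapping) -> NetworkConfig:
    pools = tuple(
        PoolSpec(p["name"], int(p["n_carbons"]), p.get("concentration"),
                 bool(p.get("dynamic", True)))
        for p in d["pools"]
    )
    transitions = tuple(
        AtomTransition(
            t["name"], tuple(t["sources"]), tuple(t["targets"]),
            tuple(((s[0], int(s[1])), (g[0], int(g[1]))) for s, g in t["atom_map"]),
            t["role"], float(t.get("weight", 1.0)))
        for t in d["transitions"]
    )
    schedule = LabelSchedule(tuple(
        Phase(float(ph["t_start"]), float(ph["t_end"]),
              tuple(sorted(ph["composition"].items())))
        for ph in d["schedule"]
    ))
    return NetworkConfig(pools, transitions, schedule)


def load_config(path) -> NetworkConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def dump_config(cfg: NetworkConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
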