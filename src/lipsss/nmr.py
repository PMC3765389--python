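"""Map glutamate isotopomer fractions to 13C NMR multiplet intensities.

A carbon's 13C resonance splits into multiplet components according to the
labeling state of its chain neighbors (|delta position| = 1).  Each multiplet
intensity is therefore a sum of isotopomer fractions; for a fixed observed
carbon the multiplet intensities partition that carbon's positional
enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network import ConfigError

__all__ = [
    "MultipletDef",
    "MultipletMeasurement",
    "NMRSample",
    "GLUTAMATE_MULTIPLETS",
    "positional_enrichment",
    "multiplet_intensities",
    "compile_multiplet",
]

LABELED = "labeled"
UNLABELED = "unlabeled"

_N_GLU = 5


@dataclass(frozen=True)
class MultipletDef:
    """One multiplet: the observed carbon plus neighbor labeling conditions.

    ``conditions`` is a union of alternatives; each alternative maps an
    adjacent carbon position to ``"labeled"``/``"unlabeled"``.  A carbon not
    mentioned is unconstrained.  (The lumped C3 doublet needs two
    alternatives: exactly one of C2/C4 labeled.)
    """

    name: str
    carbon: int
    conditions: tuple[tuple[tuple[int, str], ...], ...]


def _cond(*alternatives: Mapping[int, str]) -> tuple:
    return tuple(tuple(sorted(a.items())) for a in alternatives)


#: The eleven canonical glutamate multiplets (C2, C3, C4 are observed; the
#: paper-era datasets quantify a subset of up to nine of these).
GLUTAMATE_MULTIPLETS: tuple[MultipletDef, ...] = (
    MultipletDef("C2S", 2, _cond({1: UNLABELED, 3: UNLABELED})),
    MultipletDef("C2D12", 2, _cond({1: LABELED, 3: UNLABELED})),
    MultipletDef("C2D23", 2, _cond({1: UNLABELED, 3: LABELED})),
    MultipletDef("C2Q", 2, _cond({1: LABELED, 3: LABELED})),
    MultipletDef("C3S", 3, _cond({2: UNLABELED, 4: UNLABELED})),
    # equal C2-C3 and C3-C4 couplings: the two one-neighbor doublets overlap
    MultipletDef("C3D", 3, _cond({2: LABELED, 4: UNLABELED},
                                 {2: UNLABELED, 4: LABELED})),
    MultipletDef("C3T", 3, _cond({2: LABELED, 4: LABELED})),
    MultipletDef("C4S", 4, _cond({3: UNLABELED, 5: UNLABELED})),
    MultipletDef("C4D34", 4, _cond({3: LABELED, 5: UNLABELED})),
    MultipletDef("C4D45", 4, _cond({3: UNLABELED, 5: LABELED})),
    MultipletDef("C4Q", 4, _cond({3: LABELED, 5: LABELED})),
)

MULTIPLETS_BY_NAME = {m.name: m for m in GLUTAMATE_MULTIPLETS}


def compile_multiplet(mdef: MultipletDef, n_carbons: int = _N_GLU) -> np.ndarray:
    """Indices of the isotopomers contributing to a multiplet intensity."""
    if not 1 <= mdef.carbon <= n_carbons:
        raise ConfigError(f"multiplet {mdef.name!r}: carbon out of range")
    for alt in mdef.conditions:
        for pos, state in alt:
            if abs(pos - mdef.carbon) != 1:
                raise ConfigError(
                    f"multiplet {mdef.name!r}: coupling partner C{pos} is not"
                    f" adjacent to observed carbon C{mdef.carbon}")
            if not 1 <= pos <= n_carbons:
                raise ConfigError(
                    f"multiplet {mdef.name!r}: carbon C{pos} out of range")
            if state not in (LABELED, UNLABELED):
                raise ConfigError(
                    f"multiplet {mdef.name!r}: bad condition {state!r}")
    obs_bit = 1 << (mdef.carbon - 1)
    idx = []
    for iso in range(1 << n_carbons):
        if not iso & obs_bit:
            continue  # the observed carbon must itself be labeled
        for alt in mdef.conditions:
            ok = True
            for pos, state in alt:
                bit = bool(iso >> (pos - 1) & 1)
                if bit != (state == LABELED):
                    ok = False
                    break
            if ok:
                idx.append(iso)
                break
    return np.array(idx, dtype=np.int64)


def positional_enrichment(vec: Sequence[float], carbon: int,
                          n_carbons: int = _N_GLU) -> float:
    """Fraction of molecules with ``carbon`` labeled (sum over isotopomers
    with that carbon's bit set)."""
    if not 1 <= carbon <= n_carbons:
        raise ValueError(f"carbon must be in 1..{n_carbons}, got {carbon}")
    vec = np.asarray(vec, dtype=float)
    iso = np.arange(vec.shape[0])
    return float(vec[(iso >> (carbon - 1) & 1) == 1].sum())


def multiplet_intensities(
    vec: Sequence[float],
    defs: Sequence[MultipletDef] = GLUTAMATE_MULTIPLETS,
    n_carbons: int = _N_GLU,
) -> dict[str, float]:
    """Simulated multiplet intensities m_sim (isotopomer-fraction units)."""
    vec = np.asarray(vec, dtype=float)
    return {m.name: float(vec[compile_multiplet(m, n_carbons)].sum()) for m in defs}


@dataclass(frozen=True)
class MultipletMeasurement:
    intensity: float      # m_exp, isotopomer-fraction units
    sigma: float          # measurement SD, same units
    detected: bool = True

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not self.detected and self.intensity != 0.0:
            raise ValueError("undetected multiplets must carry intensity 0")


@dataclass(frozen=True)
class NMRSample:
    """One tissue sample's measured glutamate multiplets plus metadata.

    Zero-assigned (undetected) multiplets stay in the record with their
    noise SD; they still enter the fit.
    """

    sample_id: str
    heart_id: str
    group: str
    dry_weight_g: float
    glutamate_conc: float  # umol / g dry weight, from biochemical assay
    multiplets: Mapping[str, MultipletMeasurement] = field(default_factory=dict)

    def __post_init__(self):
        if not self.dry_weight_g > 0:
            raise ValueError("dry_weight_g must be > 0")
        if not self.glutamate_conc > 0:
            raise ValueError("glutamate_conc must be > 0")

    @property
    def multiplet_names(self) -> tuple[str, ...]:
        return tuple(self.multiplets)

    def intensity_array(self) -> np.ndarray:
        return np.array([m.intensity for m in self.multiplets.values()])

    def sigma_array(self) -> np.ndarray:
        return np.array([m.sigma for m in self.multiplets.values()])
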