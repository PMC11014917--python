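"""Model parameters: definition, validation, presets, serialization.

All quantities are in a fixed unit system: lengths in micrometres (um),
forces in piconewtons (pN), times in seconds (s).  Stiffnesses are pN/um,
rates 1/s, drag coefficients pN.s/um.  No unit conversion is performed.

The ``control`` preset describes a HeLa-like cell forming a bipolar spindle;
the ``mutant`` preset models CKAP5 (ch-TOG/XMAP215) depletion purely as a
reduction of the kMT-KT attachment spring stiffness ``K_kmt_kt``, all other
parameters identical.  Constants not fixed by direct measurement are
calibrated defaults (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "ModelParameters",
    "preset",
    "load_parameters",
    "store_parameters",
    "fingerprint",
    "ParameterError",
]


class ParameterError(ValueError):
    """Raised when a parameter file or parameter set fails validation."""


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the spindle model.

    Geometry
    --------
    r_cell : cell radius (um).
    d_cent : centrosome distance from the cell centre (um); the two poles sit
        at (-d_cent, 0, 0) and (+d_cent, 0, 0).
    n_ch : number of chromosome pairs (sister-kinetochore pairs).
    n_mt_per_pole : astral microtubules nucleated per centrosome.

    Microtubule dynamics
    --------------------
    v_g, v_s : growth / shrinkage speed (um/s).
    f_r, f_c : rescue / catastrophe frequency of free MTs (1/s).
    f_s : MT stall force (pN); force scale of the load-dependent rescue.
    f_push : cap on the polymerization push a stalled end-on tip exerts
        on the KT plate (pN).
    R_cat : length-dependent catastrophe rate constant of loaded MTs
        (1/(um.s)).
    R_cat_free : length-dependent catastrophe rate constant added to ``f_c``
        for free (searching) MTs (1/(um.s)); limits how far astral MTs
        reach across the cell.

    Forces
    ------
    A_pe : maximum polar ejection force on a chromosome arm (pN).
    L : average MT length controlling the exponential decay of the ejection
        and boundary forces (um).
    K_kmt_kt, l_kmt_kt : kMT-KT attachment spring stiffness (pN/um) and rest
        length (um).  The mutant preset lowers only K_kmt_kt.
    K_cohesion, l_cohesion : sister-KT cohesion spring stiffness and rest
        length.
    A_ch_ch : inter-chromosome inverse-square repulsion amplitude (pN.um^2).
    A_boundary : cell-boundary repulsion amplitude (pN).

    Error correction
    ----------------
    R_detach : base detachment rate constant (1/s).
    F0 : force normalisation of the detachment exponent (pN); of the order
        of the stall force, calibrated against the control census.
    beta_sign : sign of the angle exponent in the merotelic detachment
        rate, with the angle measured from the kinetochore toward its
        sister.  The calibrated default +1.0 protects kMTs aligned with
        the sister axis; -1.0 gives the literal exp(-beta) form under the
        toward-sister convention (see docs/methods.md).

    Capture & motion
    ----------------
    p_capture : probability of attachment when an MT passes within ``r_kt``
        of a kinetochore.
    r_kt : kinetochore capture radius (um).
    n_max : maximum MT occupancy per kinetochore.
    gamma_ch : drag coefficient of a chromosome body (pN.s/um); sets the
        overdamped mobility.

    Run control
    -----------
    dt : time step (s).
    t_end : simulated duration (s).
    seed : default RNG seed.
    """

    r_cell: float = 10.0
    d_cent: float = 6.0
    n_ch: int = 80
    n_mt_per_pole: int = 600

    v_g: float = 0.2
    v_s: float = 0.35
    f_r: float = 0.05
    f_c: float = 0.075
    f_s: float = 5.0
    f_push: float = 5.0
    R_cat: float = 0.06
    R_cat_free: float = 0.0

    A_pe: float = 6.0
    L: float = 5.0
    K_kmt_kt: float = 20.0
    l_kmt_kt: float = 0.1
    K_cohesion: float = 40.0
    l_cohesion: float = 1.0
    A_ch_ch: float = 7.0
    A_boundary: float = 20.0

    R_detach: float = 1.2e-2
    F0: float = 2.5
    beta_sign: float = 1.0

    p_capture: float = 1.0
    r_kt: float = 0.6
    n_max: int = 3
    gamma_ch: float = 20.0

    dt: float = 0.5
    t_end: float = 1200.0
    seed: int = 0

    def __post_init__(self) -> None:
        validate(self)

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_POSITIVE = (
    "r_cell", "d_cent", "n_ch", "n_mt_per_pole", "v_g", "v_s", "f_s", "f_push",
    "R_cat", "A_pe", "L", "K_kmt_kt", "l_kmt_kt", "K_cohesion",
    "l_cohesion", "A_ch_ch", "A_boundary", "F0", "r_kt", "n_max",
    "gamma_ch", "dt", "t_end",
)
_NONNEGATIVE = ("f_r", "f_c", "R_detach", "R_cat_free")
_INT_FIELDS = ("n_ch", "n_mt_per_pole", "n_max", "seed")


def validate(p: ModelParameters) -> None:
    """Check physical invariants; raise :class:`ParameterError` naming the
    offending field."""
    for name in _POSITIVE:
        v = getattr(p, name)
        if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
            raise ParameterError(f"{name} must be strictly positive, got {v!r}")
    for name in _NONNEGATIVE:
        v = getattr(p, name)
        if not (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0):
            raise ParameterError(f"{name} must be non-negative, got {v!r}")
    for name in _INT_FIELDS:
        v = getattr(p, name)
        if not isinstance(v, int):
            raise ParameterError(f"{name} must be an integer, got {v!r}")
    if not 0.0 <= p.p_capture <= 1.0:
        raise ParameterError(f"p_capture must lie in [0, 1], got {p.p_capture!r}")
    if p.beta_sign not in (-1.0, 1.0):
        raise ParameterError(f"beta_sign must be -1.0 or +1.0, got {p.beta_sign!r}")
    if not p.d_cent < p.r_cell:
        raise ParameterError("d_cent must be smaller than r_cell")
    if not p.r_kt < 0.2 * p.r_cell:
        raise ParameterError("r_kt must be much smaller than r_cell")
    # no MT tip may tunnel through a capture sphere in one step
    if p.v_g * p.dt >= p.r_kt:
        raise ParameterError("v_g*dt must be smaller than r_kt")
    if p.v_s * p.dt >= p.r_kt:
        raise ParameterError("v_s*dt must be smaller than r_kt")
    if not p.l_kmt_kt <= p.r_kt:
        raise ParameterError("l_kmt_kt must not exceed r_kt")


#: stiffness of the kMT-KT spring after CKAP5 depletion (pN/um); the single
#: field in which the mutant preset differs from the control.
MUTANT_K_KMT_KT = 2.0

_PRESETS = ("control", "mutant")


def preset(name: str) -> ModelParameters:
    """Return the ``control`` or CKAP5-depleted ``mutant`` parameter preset.

    The mutant differs from the control only in ``K_kmt_kt``.
    """
    if name == "control":
        return ModelParameters()
    if name == "mutant":
        return ModelParameters(K_kmt_kt=MUTANT_K_KMT_KT)
    raise ParameterError(f"unknown preset {name!r}; choose from {_PRESETS}")


def load_parameters(path: str | Path) -> ModelParameters:
    """Load parameters from a flat YAML/JSON mapping.

    Missing keys are filled from the control preset; unknown keys are
    rejected.  An empty file yields the control preset verbatim.
    """
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ParameterError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ParameterError(f"{path} must contain a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(ModelParameters)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ParameterError(f"unknown parameter keys: {', '.join(unknown)}")
    return ModelParameters(**data)


def store_parameters(p: ModelParameters, path: str | Path) -> None:
    """Write a parameter set as flat YAML; ``load_parameters`` round-trips."""
    Path(path).write_text(yaml.safe_dump(p.to_dict(), sort_keys=True))


def fingerprint(p: ModelParameters) -> str:
    """Stable 12-hex-digit identifier of a parameter set.

    Identical parameter values give identical fingerprints regardless of the
    order fields appeared in a source file; any field change changes it.
    """
    canon = json.dumps(p.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
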