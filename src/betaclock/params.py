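"""Model parameters: kinetic constants, Hill coefficients and coupling strengths.

All rates are per hour, concentrations are dimensionless (relative-expression
scale).  The reference set shipped in ``data/reference_params.yaml`` was
calibrated so that the entrained model reproduces the wild-type rodent
phenotype (nighttime feeding) and the differential clock-gene phase shift
under daytime feeding.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "PARAM_NAMES",
    "load_params",
    "save_params",
    "reference_params",
]


@dataclass
class ModelParameters:
    """Kinetic constants of the 13-variable clock/metabolism model.

    Fields group as: maximal transcription rates ``v_*`` (conc/h),
    translation rates ``k_*`` (1/h), first-order degradation constants
    ``d_*`` (1/h), PER-CRY complex formation/dissociation, Hill thresholds
    ``K_*`` (conc) with exponents ``n_*`` (>= 1), zeitgeber couplings
    (``c_glu``: glucose drive on Per transcription, ``cneur``: SCN-cue drive
    on Rev-Erb transcription), the insulin equation constants (``k_i``
    maximal secretion rate, ``d_i`` clearance), the glucose balance and the
    two-variable food-intake subsystem.
    """

    # clock transcription (maximal rates, conc/h)
    v_bmal: float = 1.0
    v_per: float = 1.0
    v_cry: float = 1.0
    v_rev: float = 1.0
    v_exo: float = 1.0
    # translation (1/h)
    k_bmal: float = 0.6
    k_per: float = 0.6
    k_cry: float = 0.6
    k_rev: float = 0.6
    k_exo: float = 0.6
    # mRNA degradation (1/h)
    d_bmal_m: float = 0.5
    d_per_m: float = 0.5
    d_cry_m: float = 0.5
    d_rev_m: float = 0.5
    d_exo_m: float = 0.5
    # protein degradation (1/h)
    d_bmal_p: float = 0.3
    d_per_p: float = 0.3
    d_cry_p: float = 0.3
    d_rev_p: float = 0.3
    d_exo_p: float = 0.3
    # PER-CRY complex
    k_assoc: float = 1.0
    k_dissoc: float = 0.1
    d_complex: float = 0.3
    # regulatory Hill terms
    K_bmal_act: float = 1.0
    n_bmal_act: float = 2.0
    K_cplx: float = 1.0
    n_cplx: float = 4.0
    K_rev_rep: float = 1.0
    n_rev_rep: float = 3.0
    K_glu_per: float = 1.5
    n_glu_per: float = 4.0
    # zeitgeber couplings
    c_glu: float = 1.0
    cneur: float = 1.4336
    # insulin secretion / clearance
    k_i: float = 1.0
    d_i: float = 0.5
    K_glu_sec: float = 1.5
    n_glu_sec: float = 4.0
    K_exo_sec: float = 1.0
    n_exo_sec: float = 4.0
    # glucose balance
    g_base: float = 0.3
    k_food_glu: float = 1.0
    d_glu: float = 0.3
    k_ins_glu: float = 0.5
    # food-intake subsystem (drive -> activator -> output)
    k_f1: float = 2.0
    d_f1: float = 2.0
    k_f2: float = 1.0
    d_f2: float = 1.0
    # SCN-cue peak time (ZT hour within the light phase)
    scn_peak: float = 6.0
    # exocytosis-gene regulation (gene-specific thresholds on the shared
    # CLOCK-BMAL1 activator and PER-CRY repressor)
    K_bmal_exo: float = 1.0
    n_bmal_exo: float = 2.0
    K_cplx_exo: float = 1.0
    n_cplx_exo: float = 4.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` on non-physical values."""
        for name in PARAM_NAMES:
            val = getattr(self, name)
            if not np.isfinite(val):
                raise ValueError(f"parameter {name!r} is not finite: {val}")
            if name == "cneur":
                if val < 0:
                    raise ValueError(f"cneur must be >= 0, got {val}")
            elif name == "scn_peak":
                if not (0.0 <= val <= 12.0):
                    raise ValueError(
                        f"scn_peak must lie in the light phase [0, 12], got {val}"
                    )
            elif name.startswith("n_"):
                if val < 1:
                    raise ValueError(f"Hill exponent {name!r} must be >= 1, got {val}")
            elif name == "c_glu":
                if val < 0:
                    raise ValueError(f"c_glu must be >= 0, got {val}")
            elif val <= 0:
                raise ValueError(f"parameter {name!r} must be > 0, got {val}")

    # -- conversions -------------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParameters":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(d)
        if missing:
            raise KeyError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)


PARAM_NAMES: tuple[str, ...] = tuple(
    f.name for f in dataclasses.fields(ModelParameters)
)


def load_params(path: str | Path) -> ModelParameters:
    """Load parameters from a flat YAML/JSON mapping; unknown keys rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key->value mapping")
    return ModelParameters.from_dict(data)


def save_params(params: ModelParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)


def reference_params() -> ModelParameters:
    """The calibrated reference parameter set shipped with the package."""
    ref = resources.files("betaclock.data").joinpath("reference_params.yaml")
    data = yaml.safe_load(ref.read_text())
    return ModelParameters.from_dict(data)
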