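"""Right-hand side of the 13-variable beta-cell clock / glucose-insulin model.

The clock is a transcriptional-translational feedback network: CLOCK-BMAL1
(represented by the BMAL1 protein) activates transcription of Per, Cry,
Rev-Erb and of a generic exocytosis factor (Exo).  PER and CRY proteins
associate into a PER-CRY complex that inhibits the *action* of CLOCK-BMAL1
(multiplicative repression of every BMAL1-activated transcription term),
while REV-ERB protein represses Bmal1 transcription.  Isoforms are merged
and no nuclear/cytoplasmic distinction is made, giving 9 clock variables.

The metabolic block: food intake raises blood glucose, insulin secretion
follows a coincidence rule -- it requires simultaneously high glucose
(f_glu) and high clock-driven exocytosis capacity (f_exo):

    d[Insulin]/dt = k_i * f_glu * f_exo - d_i * [Insulin]

and insulin in turn accelerates glucose uptake.  Glucose feeds back on the
clock through an additive activation of Per transcription, the SCN cue
through an additive activation of Rev-Erb transcription.
"""

from __future__ import annotations

import numpy as np

from .forcing import ForcingBundle
from .params import ModelParameters

__all__ = [
    "STATE_NAMES",
    "CLOCK_VARIABLES",
    "CLOCK_MRNAS",
    "METABOLIC_VARIABLES",
    "N_STATE",
    "hill_activation",
    "hill_repression",
    "f_glu",
    "f_exo",
    "insulin_derivative",
    "rhs",
]

#: state ordering used throughout the package
STATE_NAMES: tuple[str, ...] = (
    "bmal1_mRNA",
    "BMAL1_prot",
    "per_mRNA",
    "PER_prot",
    "cry_mRNA",
    "CRY_prot",
    "percry_complex",
    "rev_mRNA",
    "REV_prot",
    "glucose",
    "insulin",
    "exo_mRNA",
    "EXO_prot",
)
N_STATE = len(STATE_NAMES)

CLOCK_VARIABLES: tuple[str, ...] = STATE_NAMES[:9]
CLOCK_MRNAS: tuple[str, ...] = ("bmal1_mRNA", "per_mRNA", "cry_mRNA", "rev_mRNA")
METABOLIC_VARIABLES: tuple[str, ...] = ("glucose", "insulin", "exo_mRNA", "EXO_prot")

_IDX = {name: i for i, name in enumerate(STATE_NAMES)}


def hill_activation(x, K: float, n: float):
    """Hill activation x^n / (K^n + x^n), a saturating fraction in [0, 1]."""
    if K <= 0:
        raise ValueError(f"Hill threshold K must be > 0, got {K}")
    if n < 1:
        raise ValueError(f"Hill exponent n must be >= 1, got {n}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Hill input must be non-negative")
    r = (x / K) ** n
    out = r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def hill_repression(x, K: float, n: float):
    """Hill repression K^n / (K^n + x^n) = 1 - hill_activation(x, K, n)."""
    if K <= 0:
        raise ValueError(f"Hill threshold K must be > 0, got {K}")
    if n < 1:
        raise ValueError(f"Hill exponent n must be >= 1, got {n}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Hill input must be non-negative")
    r = (x / K) ** n
    out = 1.0 / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def f_glu(glucose, params: ModelParameters):
    """Effect of glucose on insulin secretion (saturating activation)."""
    return hill_activation(glucose, params.K_glu_sec, params.n_glu_sec)


def f_exo(exo_prot, params: ModelParameters):
    """Effect of the clock-controlled exocytosis machinery on secretion."""
    return hill_activation(exo_prot, params.K_exo_sec, params.n_exo_sec)


def insulin_derivative(insulin: float, f_glu_val: float, f_exo_val: float, params: ModelParameters) -> float:
    """Coincidence-gated secretion minus first-order clearance."""
    return params.k_i * f_glu_val * f_exo_val - params.d_i * insulin


def rhs(t: float, state: np.ndarray, params: ModelParameters, cues: ForcingBundle) -> np.ndarray:
    """Time derivative of the 13 model variables.

    ``cues`` supplies the food-intake signal and the SCN cue at time t.
    The optional attribute ``exo_transcription_override`` on ``cues``, when
    set, replaces the clock-driven Exo transcription by that constant (the
    "no clock at all" ablation).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATE,):
        raise ValueError(f"state must have {N_STATE} components, got {state.shape}")
    if not np.all(np.isfinite(state)):
        raise FloatingPointError(f"non-finite state at t={t}")

    (mb, pb, mp, pp, mc, pc, cpc, mr, pr, glu, ins, me, pe) = state
    p = params

    # shared CLOCK-BMAL1 gate: activation by BMAL1, repression of its action
    # by the PER-CRY complex
    gate = hill_activation(pb, p.K_bmal_act, p.n_bmal_act) * hill_repression(
        cpc, p.K_cplx, p.n_cplx
    )

    food = cues.food(t)
    scn = cues.scn(t)

    d = np.empty(N_STATE)
    d[0] = p.v_bmal * hill_repression(pr, p.K_rev_rep, p.n_rev_rep) - p.d_bmal_m * mb
    d[1] = p.k_bmal * mb - p.d_bmal_p * pb
    d[2] = (
        p.v_per * gate
        + p.c_glu * hill_activation(glu, p.K_glu_per, p.n_glu_per)
        - p.d_per_m * mp
    )
    d[3] = p.k_per * mp - p.k_assoc * pp * pc + p.k_dissoc * cpc - p.d_per_p * pp
    d[4] = p.v_cry * gate - p.d_cry_m * mc
    d[5] = p.k_cry * mc - p.k_assoc * pp * pc + p.k_dissoc * cpc - p.d_cry_p * pc
    d[6] = p.k_assoc * pp * pc - p.k_dissoc * cpc - p.d_complex * cpc
    d[7] = p.v_rev * gate + scn - p.d_rev_m * mr
    d[8] = p.k_rev * mr - p.d_rev_p * pr
    d[9] = p.g_base + p.k_food_glu * food - p.d_glu * glu - p.k_ins_glu * ins * glu
    d[10] = insulin_derivative(ins, f_glu(glu, p), f_exo(pe, p), p)
    exo_override = getattr(cues, "exo_transcription_override", None)
    if exo_override is None:
        exo_gate = hill_activation(pb, p.K_bmal_exo, p.n_bmal_exo) * hill_repression(
            cpc, p.K_cplx_exo, p.n_cplx_exo
        )
        d[11] = p.v_exo * exo_gate - p.d_exo_m * me
    else:
        d[11] = exo_override - p.d_exo_m * me
    d[12] = p.k_exo * me - p.d_exo_p * pe
    return d
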