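"""Registry of Budyko-type evaporative-fraction curves f(AI).

Each form predicts the long-term evapotranspiration ratio ET/P as a function
of the aridity index AI = ETp/P, together with its analytic first
derivative f'(AI) (needed by the streamflow elasticity). All bundled forms
are classical one-line curves from the catchment water-balance literature:

=============  =============================================
Schreiber      f = 1 - exp(-AI)
Ol'dekop       f = AI * tanh(1/AI)
Budyko         f = sqrt(AI * tanh(1/AI) * (1 - exp(-AI)))
Turc-Pike      f = (1 + AI^-2)^(-1/2)
Fu             f = 1 + AI - (1 + AI^w)^(1/w), w = 2.6
Zhang          f = (1 + 2 AI) / (1 + 2 AI + AI^-1)
=============  =============================================

Every form satisfies 0 <= f(AI) < 1 and f nondecreasing on AI > 0; analytic
derivatives are validated against central differences in the test suite.
The registry is an ordinary dict, so users can add or replace members.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

from .errors import ValidationError


@dataclasses.dataclass(frozen=True)
class ElasticityForm:
    """A named evaporative-fraction curve with its derivative.

    ``f`` maps AI -> predicted ET/P ratio; ``f_prime`` is df/dAI.
    ``parameter`` records the shape constant for parametric forms (Fu's w),
    ``None`` otherwise.
    """

    name: str
    f: Callable[[np.ndarray], np.ndarray]
    f_prime: Callable[[np.ndarray], np.ndarray]
    parameter: float | None = None


def _schreiber_f(ai):
    return 1.0 - np.exp(-ai)


def _schreiber_fp(ai):
    return np.exp(-ai)


def _oldekop_f(ai):
    ai = np.asarray(ai, dtype=float)
    return ai * np.tanh(1.0 / ai)


def _oldekop_fp(ai):
    ai = np.asarray(ai, dtype=float)
    t = np.tanh(1.0 / ai)
    return t - (1.0 - t * t) / ai


def _budyko_f(ai):
    return np.sqrt(_oldekop_f(ai) * _schreiber_f(ai))


def _budyko_fp(ai):
    f = _budyko_f(ai)
    return (_oldekop_fp(ai) * _schreiber_f(ai) + _oldekop_f(ai) * _schreiber_fp(ai)) / (
        2.0 * f
    )


def _turc_pike_f(ai):
    ai = np.asarray(ai, dtype=float)
    return (1.0 + ai ** -2.0) ** -0.5


def _turc_pike_fp(ai):
    ai = np.asarray(ai, dtype=float)
    return ai ** -3.0 * (1.0 + ai ** -2.0) ** -1.5


_FU_W = 2.6


def _fu_f(ai):
    ai = np.asarray(ai, dtype=float)
    return 1.0 + ai - (1.0 + ai ** _FU_W) ** (1.0 / _FU_W)


def _fu_fp(ai):
    ai = np.asarray(ai, dtype=float)
    return 1.0 - (1.0 + ai ** _FU_W) ** (1.0 / _FU_W - 1.0) * ai ** (_FU_W - 1.0)


def _zhang_f(ai):
    ai = np.asarray(ai, dtype=float)
    return (1.0 + 2.0 * ai) / (1.0 + 2.0 * ai + 1.0 / ai)


def _zhang_fp(ai):
    ai = np.asarray(ai, dtype=float)
    v = 1.0 + 2.0 * ai + 1.0 / ai
    return (1.0 + 4.0 * ai) / (ai * v) ** 2.0


#: The bundled six-member ensemble, in a stable order.
FORMS: dict[str, ElasticityForm] = {
    "schreiber": ElasticityForm("schreiber", _schreiber_f, _schreiber_fp),
    "oldekop": ElasticityForm("oldekop", _oldekop_f, _oldekop_fp),
    "budyko": ElasticityForm("budyko", _budyko_f, _budyko_fp),
    "turc_pike": ElasticityForm("turc_pike", _turc_pike_f, _turc_pike_fp),
    "fu": ElasticityForm("fu", _fu_f, _fu_fp, parameter=_FU_W),
    "zhang": ElasticityForm("zhang", _zhang_f, _zhang_fp),
}


def get_forms(selection: str | tuple[str, ...] | list[str] = "all") -> list[ElasticityForm]:
    """Resolve a selection (``"all"``, a name, or a sequence of names) to
    registered forms, preserving registry order for ``"all"``."""
    if selection == "all":
        return list(FORMS.values())
    if isinstance(selection, str):
        selection = (selection,)
    out = []
    for name in selection:
        if name not in FORMS:
            raise ValidationError(
                f"unknown elasticity form {name!r}; known: {', '.join(FORMS)}"
            )
        out.append(FORMS[name])
    return out
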