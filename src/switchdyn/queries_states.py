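"""The phenotype alphabet: Morse graphs summarized as discrete states."""

from __future__ import annotations

from enum import Enum


class MorseState(str, Enum):
    """Phenotype summary of one Morse graph's attractor set.

    Read through the phenotype node's coordinate of each fixed-point
    attractor: QS (quiescent) at 0, PS (proliferative) at >= 1.  Non-FP
    attractors never count as QS or PS.
    """

    QS_MONO = "QS"          # unique attractor, a quiescent FP
    PS_MONO = "PS"          # unique attractor, a proliferative FP
    BI_QS_PS = "B"          # both a QS-FP and a PS-FP among the attractors
    BI_QS_STAR = "B(QS,*)"  # a QS-FP plus some other FP, but no PS-FP
    BI_PS_STAR = "B(PS,*)"  # a PS-FP plus some other FP, but no QS-FP
    OTHER = "O"             # anything else (incl. non-FP attractors only)
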