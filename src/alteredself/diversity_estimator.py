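"""How many distinct inhibitory KIRs does a host need?

If a fraction f of possible iKIRs detects the event of interest (a decrease,
a halving, or a complete loss of ligands), and one detecting receptor is
enough to license an NK-cell response, the expected number of receptors per
detecting receptor is 1/f — so a host needs about ceil(1/f) distinct iKIRs
(the ``inverse`` method). The explicit alternative (``confidence``) asks for
the smallest k with 1 - (1-f)^k >= gamma, i.e. detection with probability at
least gamma when receptors are independent.
"""

from __future__ import annotations

import math

import pandas as pd

from .exceptions import ParameterError

#: Events a receptor can detect, as named in sweep summary columns.
DETECTION_EVENTS = ("decrease", "decrease_ge50", "disappeared")


def required_kir_count(f: float, method: str = "inverse", gamma: float = 0.95) -> int:
    """Number of distinct iKIRs needed when a fraction *f* of iKIRs detects the event.

    ``method="inverse"`` returns ceil(1/f); ``method="confidence"`` returns
    the smallest k with 1 - (1-f)^k >= gamma.
    """
    if not (0.0 < f <= 1.0):
        raise ParameterError(f"detection fraction f must be in (0, 1], got {f}")
    if method == "inverse":
        return math.ceil(1.0 / f)
    if method == "confidence":
        if not (0.0 < gamma < 1.0):
            raise ParameterError(f"gamma must be in (0, 1), got {gamma}")
        if f == 1.0:
            return 1
        # smallest k with 1 - (1-f)^k >= gamma
        k = 1
        miss = 1.0 - f
        while 1.0 - miss ** k < gamma:
            k += 1
        return k
    raise ParameterError(f"method must be 'inverse' or 'confidence', got {method!r}")


def binding_probability(n_binders: int, n_total: int, ndigits: int = 1) -> float:
    """Empirical per-peptide recognition probability from a binding screen.

    E.g. 13 binders among 59 peptides with unique P7/P8 pairs gives a
    specificity estimate of 0.2 after rounding to one decimal.
    """
    if n_total <= 0 or n_binders < 0 or n_binders > n_total:
        raise ParameterError(f"invalid binder counts {n_binders}/{n_total}")
    return round(n_binders / n_total, ndigits)


def required_counts_table(
    sweep: pd.DataFrame,
    events=DETECTION_EVENTS,
    gamma: float = 0.95,
) -> pd.DataFrame:
    """Tabulate required iKIR counts per specificity p and detection event.

    Consumes a sweep summary frame (columns ``p`` and ``frac_<event>``);
    events with zero detection fraction get NaN (no finite receptor count
    achieves detection).
    """
    rows = []
    for _, sweep_row in sweep.iterrows():
        for event in events:
            f = float(sweep_row[f"frac_{event}"])
            row = {"p": float(sweep_row["p"]), "event": event, "f": f}
            if f > 0.0:
                row["k_inverse"] = required_kir_count(f, method="inverse")
                row["k_confidence"] = required_kir_count(f, method="confidence", gamma=gamma)
            else:
                row["k_inverse"] = float("nan")
                row["k_confidence"] = float("nan")
            row["gamma"] = gamma
            rows.append(row)
    return pd.DataFrame(rows, columns=["p", "event", "f", "k_inverse", "k_confidence", "gamma"])
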