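"""Deterministic bench-readout calculators.

Three small computations shared by the gradient and expression analyses:

* :func:`fraction_percentages` — convert per-fraction qPCR Ct values from a
  sucrose gradient into percentages of the total RNA detected across the
  gradient, with the gradient input Ct as the reference (ΔCt method).
* :func:`ddct_relative_expression` — classic ΔΔCt fold change with a fixed
  amplification efficiency of 2 per cycle.
* :func:`densitometry_fold_change` — western-blot band quantification
  normalised to a loading control and expressed relative to a control lane.

Non-detected qPCR fractions are encoded as ``nan`` (never Ct = 0, which
would silently explode through ``2**Ct``).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "NOT_DETECTED",
    "fraction_percentages",
    "ddct_relative_expression",
    "densitometry_fold_change",
]

#: Sentinel for a qPCR fraction with no amplification signal.
NOT_DETECTED = float("nan")


def fraction_percentages(ct: np.ndarray | list, ct_input: float) -> np.ndarray:
    """Percent of total detected RNA per gradient fraction from Ct values.

    Each fraction's quantity relative to the gradient input is
    ``q_f = 2**(ct_input - ct_f)`` (one cycle = one doubling); percentages
    are ``100 * q_f / sum(q)`` over detected fractions.  Non-detected
    fractions (``nan``) report 0%.

    Parameters
    ----------
    ct
        Per-fraction threshold cycles; ``nan`` marks non-detected fractions.
    ct_input
        Ct of the unfractionated gradient input (the ΔCt reference).

    Returns
    -------
    numpy.ndarray
        Percent per fraction, summing to 100 over detected fractions.

    Raises
    ------
    ValueError
        If every fraction is non-detected.
    """
    ct = np.asarray(ct, dtype=float)
    detected = np.isfinite(ct)
    if not detected.any():
        raise ValueError("all gradient fractions are non-detected; no reference signal")
    q = np.zeros_like(ct)
    q[detected] = np.exp2(float(ct_input) - ct[detected])
    return 100.0 * q / q.sum()


def ddct_relative_expression(
    ct_target: float, ct_ref: float, ct_target_ctrl: float, ct_ref_ctrl: float
) -> float:
    """Relative expression by the ΔΔCt method.

    ``2**-((ct_target - ct_ref) - (ct_target_ctrl - ct_ref_ctrl))`` with the
    reference gene (e.g. GAPDH) correcting for template amount.  Replicate
    Cts should be averaged by the caller before transformation.
    """
    ddct = (ct_target - ct_ref) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def densitometry_fold_change(
    target: float, loading: float, target_ctrl: float, loading_ctrl: float
) -> float:
    """Band intensity normalised to a loading control, relative to control.

    Returns ``(target/loading) / (target_ctrl/loading_ctrl)``; all four
    intensities must be positive.
    """
    for name, v in (
        ("target", target),
        ("loading", loading),
        ("target_ctrl", target_ctrl),
        ("loading_ctrl", loading_ctrl),
    ):
        if not v > 0:
            raise ValueError(f"band intensity {name!r} must be positive, got {v}")
    return (target / loading) / (target_ctrl / loading_ctrl)
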