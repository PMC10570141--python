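"""Forced-turnover and senescence quantification.

Utilities for the depletion-repopulation arithmetic (cumulative microglial
divisions), relative telomere length from qPCR quantification cycles,
Sholl-curve morphology (area under the intersection profile), the
density-over-complexity senescence index, and the Y-maze spontaneous
alternation rate.
"""

from __future__ import annotations

import math

import numpy as np

from .containers import ShollProfile, TelomereAssay, TurnoverRecord, ValidationError

__all__ = ["cumulative_divisions", "telomere_length", "sholl_auc",
           "senescence_index", "alternation_rate"]


def cumulative_divisions(record: TurnoverRecord) -> float:
    """Total cell divisions implied by depletion-repopulation rounds.

    Each round in which a residual density ``res`` repopulates to
    ``rec`` requires ``log2(rec / res)`` population doublings, so the
    total is the sum over rounds.  Exact arithmetic; additive over
    concatenated records.
    """
    return float(sum(math.log2(rec / res) for res, rec in record.rounds))


def telomere_length(assay: TelomereAssay, convention: str = "as_printed") -> float:
    """Relative telomere length in kb from qPCR quantification cycles.

    ``as_printed`` applies the source formula verbatim:

        ref_length * 2 ** ((Cq_t_tel - Cq_r_tel) - (Cq_t_scr - Cq_r_scr))

    ``standard`` negates the exponent, the conventional 2**(-ddCq) form
    in which more template (lower Cq) means longer telomeres.  The two
    agree whenever the double difference is zero.
    """
    if convention not in {"as_printed", "standard"}:
        raise ValidationError(f"unknown convention {convention!r}")
    ddcq = ((assay.cq_target_tel - assay.cq_ref_tel)
            - (assay.cq_target_scr - assay.cq_ref_scr))
    if convention == "standard":
        ddcq = -ddcq
    return assay.ref_length_kb * 2.0 ** ddcq


def sholl_auc(profile: ShollProfile) -> float:
    """Trapezoidal area under the Sholl curve (intersections * um).

    Integrates the intersection counts over radius from the first to the
    last ring; no extrapolation toward radius zero.
    """
    if profile.radii.size < 2:
        raise ValidationError("need at least 2 radii for an AUC")
    return float(np.trapezoid(np.asarray(profile.intersections, dtype=float),
                              profile.radii))


def senescence_index(density: float, auc: float) -> float:
    """Microglial density divided by morphological complexity (Sholl AUC).

    Higher values indicate denser, less ramified (aged-like) populations.
    """
    if auc <= 0:
        raise ValidationError("Sholl AUC must be positive")
    if density < 0:
        raise ValidationError("density must be nonnegative")
    return density / auc


def alternation_rate(entries) -> float:
    """Y-maze correct alternation rate as a percentage.

    A correct alternation is a window of three consecutive arm entries
    visiting three distinct arms; the rate is the number of such
    (overlapping) windows divided by (total entries - 2), times 100.
    """
    entries = list(entries)
    if len(entries) < 3:
        raise ValidationError("need at least 3 arm entries")
    bad = sorted({e for e in entries if e not in {"A", "B", "C"}})
    if bad:
        raise ValidationError(f"arm label(s) outside {{A, B, C}}: {bad}")
    correct = sum(
        1 for i in range(len(entries) - 2)
        if len({entries[i], entries[i + 1], entries[i + 2]}) == 3
    )
    return 100.0 * correct / (len(entries) - 2)
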