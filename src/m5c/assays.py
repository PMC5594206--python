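"""Bench-assay calculators: EMSA binding ratio and qPCR 2^(-ddCt) export ratio."""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass
class GelQuantification:
    bound_intensity: float  # RNA-protein band, arbitrary units
    free_intensity: float  # free RNA band, arbitrary units


def emsa_binding_ratio(q: GelQuantification) -> float:
    """Fraction of probe bound: bound / (free + bound)."""
    if q.bound_intensity < 0 or q.free_intensity < 0:
        raise ValueError("band intensities must be non-negative")
    total = q.bound_intensity + q.free_intensity
    if total == 0:
        raise ValueError("both band intensities are zero")
    return q.bound_intensity / total


@dataclass
class DdctInput:
    """Ct values for target and reference gene in cytoplasmic and nuclear
    fractions, for a treatment and a control condition."""
    ct_target_cyto_treat: float
    ct_ref_cyto_treat: float
    ct_target_nuc_treat: float
    ct_ref_nuc_treat: float
    ct_target_cyto_ctrl: float
    ct_ref_cyto_ctrl: float
    ct_target_nuc_ctrl: float
    ct_ref_nuc_ctrl: float


def relative_cn_ratio(d: DdctInput) -> float:
    """Relative fold change of the cytoplasmic/nuclear ratio, 2^(-ddCt).

    Per condition: dCt = (Ct_target - Ct_ref) in each compartment, and
    d(C/N) = dCt_cyto - dCt_nuc. ddCt = d(C/N)_treatment - d(C/N)_control.
    Positive ddCt means reduced relative export (fold < 1).
    """
    for name, v in vars(d).items():
        if not math.isfinite(v):
            raise ValueError(f"non-finite Ct value: {name}")
    dcn_treat = ((d.ct_target_cyto_treat - d.ct_ref_cyto_treat)
                 - (d.ct_target_nuc_treat - d.ct_ref_nuc_treat))
    dcn_ctrl = ((d.ct_target_cyto_ctrl - d.ct_ref_cyto_ctrl)
                - (d.ct_target_nuc_ctrl - d.ct_ref_nuc_ctrl))
    ddct = dcn_treat - dcn_ctrl
    return 2.0 ** (-ddct)
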