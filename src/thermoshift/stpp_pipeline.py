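"""Single-tube ramp readout: base-abundance correction and hit calling.

In the single-tube layout every condition x replicate contributes a ramped
"test" channel and a 37 C "control" channel measured in the same plex.  The
control channels carry only base-abundance differences between conditions, so
the per-protein control-batch log2 fold change (treated minus untreated,
averaged over replicates) is added to the untreated test channels before
differential testing: what remains of the treated-vs-untreated test contrast
is then attributable to differential thermal denaturation.

A hit passes both an adjusted-p and an absolute fold-change threshold
(defaults |log2 FC| > 0.5, adjusted p < 0.001).  Because the correction
itself can manufacture apparent enrichment for proteins whose abundance
difference dominates, hits whose control-batch fold change opposes and
largely accounts for their corrected fold change are flagged as
correction-driven rather than thermally stabilized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_filters import ChannelMeta, DesignError, IntensityMatrix
from .stats_norm import moderated_ttest

DEFAULT_FC_THRESHOLD = 0.5
DEFAULT_P_THRESHOLD = 0.001
DEFAULT_CORRECTION_THETA = 0.5


@dataclass(frozen=True)
class StppDesign:
    """Validated channel-index bookkeeping for a single-tube layout."""

    test_treated: tuple[int, ...]
    test_untreated: tuple[int, ...]
    control_treated: tuple[int, ...]
    control_untreated: tuple[int, ...]

    @classmethod
    def from_channels(cls, channels: tuple[ChannelMeta, ...]) -> "StppDesign":
        by_key: dict[tuple[str, str], dict[int, int]] = {}
        for i, ch in enumerate(channels):
            if ch.role not in ("test", "control"):
                raise DesignError(
                    f"channel {ch.name!r} has role {ch.role!r}; a single-tube "
                    "layout needs test/control roles (is this a TPP table?)"
                )
            key = (ch.condition, ch.role)
            slot = by_key.setdefault(key, {})
            if ch.replicate in slot:
                raise DesignError(
                    f"duplicate channel for condition={ch.condition}, "
                    f"role={ch.role}, replicate={ch.replicate}"
                )
            slot[ch.replicate] = i

        reps = None
        for cond in ("treated", "untreated"):
            for role in ("test", "control"):
                slot = by_key.get((cond, role))
                if not slot:
                    raise DesignError(f"missing channels for condition={cond}, role={role}")
                if reps is None:
                    reps = sorted(slot)
                elif sorted(slot) != reps:
                    raise DesignError(
                        f"replicates for condition={cond}, role={role} do not "
                        "match the other condition/role combinations"
                    )
        assert reps is not None
        pick = lambda cond, role: tuple(by_key[(cond, role)][r] for r in reps)
        return cls(pick("treated", "test"), pick("untreated", "test"),
                   pick("treated", "control"), pick("untreated", "control"))

    @property
    def n_replicates(self) -> int:
        return len(self.test_treated)


def abundance_correction(
    matrix: IntensityMatrix,
    design: StppDesign | None = None,
    replicate_matched: bool = True,
) -> tuple[IntensityMatrix, np.ndarray]:
    """Add the control-batch log2 fold change to the untreated test channels.

    Per protein and replicate, the treated-minus-untreated control-channel
    difference is added to that replicate's untreated test channel (with
    ``replicate_matched=False``, the replicate-mean difference Delta is added
    uniformly instead).  Treated test channels and all control channels are
    unchanged.  Returns the corrected matrix and the per-protein mean Delta.

    The replicate-matched form is the default because it keeps the downstream
    test calibrated: the sampling noise of the correction then shows up in
    the within-group variance of the corrected channels, where the moderated
    test can see it.  Adding the mean Delta uniformly shifts the contrast by
    an error the variance estimate knows nothing about and inflates the null
    t-statistics by about sqrt(2).
    """
    if design is None:
        design = StppDesign.from_channels(matrix.channels)
    x = matrix.intensities
    ctrl_diff = x[:, list(design.control_treated)] - x[:, list(design.control_untreated)]
    delta = ctrl_diff.mean(axis=1)

    corrected = x.copy()
    if replicate_matched:
        for r, j in enumerate(design.test_untreated):
            corrected[:, j] = x[:, j] + ctrl_diff[:, r]
    else:
        for j in design.test_untreated:
            corrected[:, j] = x[:, j] + delta
    return matrix.with_intensities(corrected), delta


def call_stpp_hits(
    matrix: IntensityMatrix,
    design: StppDesign | None = None,
    control_log2fc: np.ndarray | None = None,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Moderated differential test of treated vs (corrected) untreated test
    channels, with two-threshold hit calling.

    Returns a DataFrame sorted by adjusted p with columns ``protein_id``,
    ``gene_name``, ``log2fc``, ``t``, ``p``, ``p_adj``, ``control_log2fc``,
    ``hit``, ``correction_driven`` (all false until
    :func:`flag_correction_driven` runs).  A hit satisfies both
    adjusted p < ``p_threshold`` and |log2fc| > ``fc_threshold``.
    """
    if design is None:
        design = StppDesign.from_channels(matrix.channels)
    result = moderated_ttest(matrix, design.test_treated, design.test_untreated,
                             intensity_trend=True,
                             extra_groups=(design.control_treated, design.control_untreated))
    if control_log2fc is None:
        control_log2fc = np.zeros(matrix.n_proteins)
    table = pd.DataFrame({
        "protein_id": matrix.protein_ids,
        "gene_name": matrix.gene_names,
        "log2fc": result.log2fc,
        "t": result.t,
        "p": result.p,
        "p_adj": result.p_adj,
        "control_log2fc": np.asarray(control_log2fc, dtype=float),
    })
    table["hit"] = (table["p_adj"] < p_threshold) & (table["log2fc"].abs() > fc_threshold)
    table["correction_driven"] = False
    return table.sort_values("p_adj", kind="stable").reset_index(drop=True)


def flag_correction_driven(table: pd.DataFrame, theta: float = DEFAULT_CORRECTION_THETA) -> pd.DataFrame:
    """Flag hits whose enrichment is mostly manufactured by the correction.

    A negative control-batch fold change Delta inflates the corrected fold
    change (and vice versa), so a hit is flagged when sign(Delta) opposes the
    corrected log2 FC and |Delta| >= theta * |log2 FC|.  Non-hits are never
    flagged; Delta = 0 never flags.
    """
    out = table.copy()
    delta = out["control_log2fc"].to_numpy(dtype=float)
    fc = out["log2fc"].to_numpy(dtype=float)
    opposing = (delta * fc < 0)
    dominant = np.abs(delta) >= theta * np.abs(fc)
    out["correction_driven"] = out["hit"].to_numpy(dtype=bool) & opposing & dominant
    return out


def run_stpp(
    matrix: IntensityMatrix,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    theta: float = DEFAULT_CORRECTION_THETA,
    replicate_matched: bool = True,
) -> pd.DataFrame:
    """Full single-tube readout on a QC-filtered raw matrix: variance
    stabilization, base-abundance correction, moderated testing, hit calling,
    and correction-driven flagging.

    Normalization is grouped by heating role (ramped test channels together,
    37 C control channels together): the two roles have systematically
    different signal composition — in the test channels a sizable fraction of
    the proteome sits at the noise floor — and the glog calibration is only
    valid within channels of like composition, exactly as per-temperature
    normalization handles the decreasing signal up the ladder.
    """
    from .stats_norm import variance_stabilize

    design = StppDesign.from_channels(matrix.channels)
    groups = {
        "test": design.test_treated + design.test_untreated,
        "control": design.control_treated + design.control_untreated,
    }
    transformed, _ = variance_stabilize(matrix, groups=groups)
    corrected, delta = abundance_correction(transformed, design, replicate_matched=replicate_matched)
    table = call_stpp_hits(corrected, design, control_log2fc=delta,
                           fc_threshold=fc_threshold, p_threshold=p_threshold)
    return flag_correction_driven(table, theta=theta)
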