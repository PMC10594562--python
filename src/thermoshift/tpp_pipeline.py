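"""Temperature-ladder (2D-TPP) readout: abundance and stability scores.

For each protein the treated-vs-untreated log2 fold change is computed at
every ladder temperature.  The *abundance score* is the mean fold change at
the two lowest temperatures, where essentially nothing has denatured — a
proxy for expression-level differences.  The *stability score* is the sum
over all temperatures of (fold change minus abundance score): exactly zero
for a pure abundance change, positive for drug-stabilized proteins whose
soluble fraction persists to higher temperatures, negative for destabilized
ones.

Scores are computed per replicate, tested against zero with the moderated
one-sample machinery, assigned a tail-area FDR on the replicate-mean score,
and classified: "hit" for score > 3 at FDR < 0.01, "candidate" for score > 2
at FDR < 0.05 (hit takes precedence), otherwise "none".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_filters import DesignError, IntensityMatrix
from .stats_norm import moderated_one_sample, score_fdr

HIT_SCORE, HIT_FDR = 3.0, 0.01
CANDIDATE_SCORE, CANDIDATE_FDR = 2.0, 0.05
N_BASELINE_TEMPERATURES = 2


@dataclass(frozen=True)
class FoldChangeProfile:
    """Per-protein log2 fold changes across the ladder, ascending in T.

    Unsorted input ladders are sorted internally (with the fold changes
    permuted to match), so downstream scores are permutation-invariant.
    """

    temperatures: tuple[float, ...]
    log2fc: tuple[float, ...]

    def __post_init__(self) -> None:
        temps = np.asarray(self.temperatures, dtype=float)
        fc = np.asarray(self.log2fc, dtype=float)
        if temps.ndim != 1 or temps.shape != fc.shape:
            raise DesignError("temperatures and log2fc must be 1-D and equal length")
        if np.unique(temps).size != temps.size:
            raise DesignError("ladder temperatures must be distinct")
        order = np.argsort(temps, kind="stable")
        object.__setattr__(self, "temperatures", tuple(temps[order]))
        object.__setattr__(self, "log2fc", tuple(fc[order]))


def abundance_score(profile: FoldChangeProfile) -> float:
    """Mean log2 fold change at the two lowest ladder temperatures."""
    if len(profile.temperatures) < N_BASELINE_TEMPERATURES:
        raise DesignError("need at least 2 ladder temperatures")
    return float(np.mean(profile.log2fc[:N_BASELINE_TEMPERATURES]))


def stability_score(profile: FoldChangeProfile) -> float:
    """Sum over all ladder temperatures of (log2 FC minus abundance score).

    Invariant to adding any constant to the whole profile and linear in the
    profile; a constant profile scores exactly zero.
    """
    ab = abundance_score(profile)
    return float(np.sum(np.asarray(profile.log2fc) - ab))


def _scores_from_array(fc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (abundance, stability) scores for an array whose last axis
    is the ascending temperature ladder."""
    ab = fc[..., :N_BASELINE_TEMPERATURES].mean(axis=-1)
    stab = (fc - ab[..., None]).sum(axis=-1)
    return ab, stab


def replicate_fold_changes(matrix: IntensityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate fold-change profiles from a normalized TPP matrix.

    Returns (temperatures ascending, array proteins x replicates x
    temperatures) of treated-minus-untreated transformed intensities,
    pairing replicates by number within each temperature.  An incomplete
    ladder (a missing condition/replicate at any temperature) is a
    :class:`DesignError`.
    """
    temps = sorted({ch.temperature for ch in matrix.channels if ch.temperature is not None})
    if len(temps) < 2:
        raise DesignError("TPP layout needs at least 2 ladder temperatures")
    reps = sorted({ch.replicate for ch in matrix.channels})

    fc = np.empty((matrix.n_proteins, len(reps), len(temps)))
    for ti, temp in enumerate(temps):
        for ri, rep in enumerate(reps):
            treated = matrix.channel_indices(condition="treated", replicate=rep, temperature=temp)
            untreated = matrix.channel_indices(condition="untreated", replicate=rep, temperature=temp)
            if len(treated) != 1 or len(untreated) != 1:
                raise DesignError(
                    f"incomplete ladder: need exactly one treated and one "
                    f"untreated channel at T={temp} C, replicate {rep}"
                )
            fc[:, ri, ti] = matrix.intensities[:, treated[0]] - matrix.intensities[:, untreated[0]]
    return np.asarray(temps, dtype=float), fc


def mean_profile(matrix: IntensityMatrix, protein_row: int) -> FoldChangeProfile:
    """Replicate-averaged fold-change profile for one protein."""
    temps, fc = replicate_fold_changes(matrix)
    return FoldChangeProfile(tuple(temps), tuple(fc[protein_row].mean(axis=0)))


def score_tpp(
    matrix: IntensityMatrix,
    hit_score: float = HIT_SCORE,
    hit_fdr: float = HIT_FDR,
    candidate_score: float = CANDIDATE_SCORE,
    candidate_fdr: float = CANDIDATE_FDR,
) -> pd.DataFrame:
    """Score a per-temperature-normalized TPP matrix.

    Computes per-replicate abundance and stability scores, a moderated
    one-sample test of the replicate stability scores against zero, a
    tail-area FDR on the replicate-mean stability score, and the two-tier
    classification.  Returns a DataFrame sorted by FDR with columns
    ``protein_id``, ``gene_name``, ``abundance_score``, ``stability_score``,
    ``t``, ``p``, ``fdr``, ``classification``.
    """
    if matrix.scale != "glog2":
        raise DesignError("score_tpp expects a variance-stabilized matrix")
    _temps, fc = replicate_fold_changes(matrix)
    if fc.shape[1] < 2:
        raise DesignError("need at least 2 replicates per condition")
    ab_rep, stab_rep = _scores_from_array(fc)  # proteins x replicates

    test = moderated_one_sample(stab_rep)
    stab_mean = stab_rep.mean(axis=1)
    fdr = score_fdr(stab_mean)

    classification = np.full(matrix.n_proteins, "none", dtype=object)
    candidate = (stab_mean > candidate_score) & (fdr < candidate_fdr)
    classification[candidate] = "candidate"
    hit = (stab_mean > hit_score) & (fdr < hit_fdr)
    classification[hit] = "hit"

    table = pd.DataFrame({
        "protein_id": matrix.protein_ids,
        "gene_name": matrix.gene_names,
        "abundance_score": ab_rep.mean(axis=1),
        "stability_score": stab_mean,
        "t": test.t,
        "p": test.p,
        "fdr": fdr,
        "classification": classification,
    })
    return table.sort_values(["fdr", "p"], kind="stable").reset_index(drop=True)


def run_tpp(matrix: IntensityMatrix, **thresholds) -> pd.DataFrame:
    """Full ladder readout on a QC-filtered raw matrix: per-temperature
    variance stabilization followed by :func:`score_tpp`."""
    from .stats_norm import variance_stabilize

    temps = sorted({ch.temperature for ch in matrix.channels if ch.temperature is not None})
    if not temps:
        raise DesignError("run_tpp needs a TPP layout (temperature-role channels)")
    groups = {
        f"T{temp:g}": tuple(i for i, ch in enumerate(matrix.channels)
                            if ch.temperature is not None and abs(ch.temperature - temp) < 1e-9)
        for temp in temps
    }
    transformed, _ = variance_stabilize(matrix, groups=groups)
    return score_tpp(transformed, **thresholds)
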