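"""Leave-one-out marker discovery.

For a discovery cohort of n samples the loop runs n rounds.  Each round
holds out one sample, runs the two-phase screen on the remaining n-1
samples, fits a Youden-optimal abundance cutoff per surviving candidate on
those same n-1 samples, and classifies the held-out sample (case iff its
abundance >= the round's cutoff).  The final marker set is the intersection
of all n candidate lists with instrument-contaminant compounds removed;
per-marker LOOCV accuracy/sensitivity/specificity pools the n held-out
predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import youden_threshold
from .datamodel import CASE, CONTROL, CompoundRecord, ProfileMatrix
from .screening import screen_arrays


@dataclass(frozen=True)
class CandidateRound:
    """One leave-one-out round.

    ``candidates`` holds (compound_id, training threshold) for every
    compound passing both screening phases on the round's n-1 training
    samples; ``heldout_predictions`` maps each candidate to the predicted
    group of the held-out sample.
    """

    round_index: int
    heldout_sample_id: str
    heldout_true_group: str
    candidates: tuple[tuple[str, float], ...]
    heldout_predictions: dict[str, str]


@dataclass(frozen=True)
class MarkerSet:
    """Compounds surviving every round's screen, contaminants excluded.

    Ordered by ascending rank-sum p-value on the full discovery cohort.
    """

    marker_ids: tuple[str, ...]


def run_loocv(
    pm_discovery: ProfileMatrix, alpha: float = 0.05, cutoff: float = 0.6
) -> list[CandidateRound]:
    """Run the full leave-one-out screening loop (one round per sample)."""
    n = pm_discovery.n_samples
    if n < 4:
        raise ValueError("discovery cohort must have at least 4 samples")
    abundance = pm_discovery.abundance
    case_mask = pm_discovery.case_mask
    compound_ids = pm_discovery.compound_ids

    rounds: list[CandidateRound] = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        train_mask = case_mask[keep]
        if train_mask.all() or not train_mask.any():
            raise ValueError(
                f"round {i}: training set lost a group after holding out "
                f"{pm_discovery.sample_ids[i]!r}"
            )
        train_abund = abundance[:, keep]
        _, _, _, pass2, _ = screen_arrays(train_abund, train_mask, alpha, cutoff)

        candidates = []
        predictions = {}
        heldout_value_row = abundance[:, i]
        for ci in np.flatnonzero(pass2):
            row = train_abund[ci]
            choice = youden_threshold(row[train_mask], row[~train_mask])
            thr = choice.threshold
            candidates.append((compound_ids[ci], thr))
            predictions[compound_ids[ci]] = (
                CASE if heldout_value_row[ci] >= thr else CONTROL
            )
        rounds.append(
            CandidateRound(
                round_index=i,
                heldout_sample_id=pm_discovery.sample_ids[i],
                heldout_true_group=str(pm_discovery.groups[i]),
                candidates=tuple(candidates),
                heldout_predictions=predictions,
            )
        )
    return rounds


def intersect_and_exclude(
    rounds: list[CandidateRound],
    compounds: list[CompoundRecord],
    pm_discovery: ProfileMatrix | None = None,
) -> MarkerSet:
    """Intersect candidate lists across rounds and drop contaminants.

    Members must appear in every round's candidate list; compounds flagged
    ``is_contaminant`` are then removed.  When ``pm_discovery`` is given,
    markers are ordered by ascending rank-sum p-value on the full discovery
    cohort; otherwise by the minimum per-round threshold's compound order.
    An empty intersection yields an empty set with a warning, not an error.
    """
    if not rounds:
        raise ValueError("at least one round is required")
    common: set[str] | None = None
    for rnd in rounds:
        ids = {cid for cid, _ in rnd.candidates}
        common = ids if common is None else common & ids
    by_id = {c.compound_id: c for c in compounds}
    kept = {cid for cid in common if not by_id[cid].is_contaminant}
    if not kept:
        warnings.warn("marker intersection is empty", stacklevel=2)
        return MarkerSet(())

    if pm_discovery is not None:
        from .screening import wilcoxon_rank_sum

        def sort_key(cid: str):
            case_vals, control_vals = pm_discovery.group_values(cid)
            return (wilcoxon_rank_sum(case_vals, control_vals), cid)

        ordered = sorted(kept, key=sort_key)
    else:
        ordered = sorted(kept)
    return MarkerSet(tuple(ordered))


def summarize_marker_performance(
    rounds: list[CandidateRound], marker_set: MarkerSet
) -> pd.DataFrame:
    """Pooled held-out performance per marker over all LOOCV rounds.

    Accuracy = correct / n; sensitivity over true cases; specificity over
    true controls.  Every marker must be present in every round (the
    marker-set invariant); a missing one is an error.
    """
    n = len(rounds)
    records = []
    for cid in marker_set.marker_ids:
        tp = fp = tn = fn = 0
        for rnd in rounds:
            if cid not in rnd.heldout_predictions:
                raise ValueError(
                    f"marker {cid!r} missing from round {rnd.round_index}"
                )
            pred = rnd.heldout_predictions[cid]
            truth = rnd.heldout_true_group
            if truth == CASE:
                tp += pred == CASE
                fn += pred != CASE
            else:
                tn += pred == CONTROL
                fp += pred != CONTROL
        records.append(
            {
                "compound_id": cid,
                "accuracy": (tp + tn) / n,
                "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
                "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            }
        )
    return pd.DataFrame(records)


def rounds_table(rounds: list[CandidateRound]) -> pd.DataFrame:
    """Flat per-round candidate listing (TSV-ready)."""
    rows = []
    for rnd in rounds:
        for cid, thr in rnd.candidates:
            rows.append(
                {
                    "round": rnd.round_index,
                    "heldout_sample": rnd.heldout_sample_id,
                    "compound_id": cid,
                    "threshold": thr,
                    "prediction": rnd.heldout_predictions[cid],
                    "truth": rnd.heldout_true_group,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["round", "heldout_sample", "compound_id", "threshold", "prediction", "truth"],
    )
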