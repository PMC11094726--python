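"""Score atom-level explanations against ground-truth alert atoms, and neuron
diagnostics.

The attribution ROC-AUC of an explanation ranks the compound's atoms by
attribution and asks how well that ranking separates the ground-truth alert
atoms (the union of atoms over all fired alerts) from the rest; ties get the
usual midrank treatment.  The score is undefined when every atom (or no atom)
belongs to the ground truth, since no false-positive rate exists.  Explanation
quality is reported for true-positive compounds only: for a false negative the
model never predicted toxicity, so no explanation of toxicity can be expected.

Per-alert aggregation restricts to compounds matching a single alert (after an
optional alert-merge map for alerts that systematically co-occur) and averages
their AUCs, then summarizes each method by the median AUC and the fraction of
compounds (and alerts) reaching 0.8.

Neuron diagnostics: pairwise Pearson correlations of compound activations
within/between hidden layers, and each neuron scored as a stand-alone
classifier (activation as score) by ROC-AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .attribution import Explanation
from .chem import Molecule
from .network import TrainedModel

__all__ = [
    "UndefinedAUCError",
    "attribution_auc",
    "evaluate_explanations",
    "neuron_correlations",
    "neuron_classifier_auc",
    "CorrelationReport",
]


class UndefinedAUCError(ValueError):
    """No ROC-AUC exists (one of the two atom/label classes is empty)."""


def attribution_auc(atom_values: Sequence[float] | np.ndarray, truth: set[int]) -> float:
    """Rank-based (midrank-tie) ROC-AUC of atom attributions against the
    ground-truth atom set.  Raises :class:`UndefinedAUCError` when the truth
    set is empty or covers every atom."""
    values = np.asarray(atom_values, dtype=float)
    truth = set(truth)
    n = values.size
    if not truth or len(truth) >= n:
        raise UndefinedAUCError(
            "attribution AUC needs at least one ground-truth and one other atom"
        )
    if truth - set(range(n)):
        raise ValueError("truth contains out-of-range atom indices")
    y = np.zeros(n, dtype=int)
    y[sorted(truth)] = 1
    return float(roc_auc_score(y, values))


@dataclass
class EvalRecord:
    compound_id: str
    predicted_class: int
    actual_class: int
    cell: str  # TP / FP / TN / FN
    attribution_auc: float | None
    alert_ids: list[str]


def _confusion_cell(actual: int, predicted: int) -> str:
    return {(1, 1): "TP", (0, 1): "FP", (0, 0): "TN", (1, 0): "FN"}[(actual, predicted)]


def evaluate_explanations(
    explanations: Sequence[Explanation],
    molecules: Sequence[Molecule],
    threshold: float = 0.5,
    merge_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-compound and per-alert explanation quality tables.

    ``merge_map`` renames alert ids before the single-alert restriction, for
    alerts that systematically co-occur with a parent alert.  Returns
    (compound table, per-alert table, summary).  Attribution AUC is computed
    for TP compounds only; compounds whose ground truth is undefined (all or
    no atoms) keep a missing AUC.
    """
    merge_map = dict(merge_map or {})
    by_id = {m.id: m for m in molecules}
    rows = []
    for exp in explanations:
        mol = by_id.get(exp.compound_id)
        if mol is None:
            raise ValueError(f"no molecule for explanation {exp.compound_id!r}")
        if mol.label is None:
            continue
        actual = int(mol.label)
        predicted = int(exp.predicted_proba >= threshold)
        cell = _confusion_cell(actual, predicted)
        truth = mol.alert_atom_union()
        auc = None
        if cell == "TP" and truth:
            try:
                auc = attribution_auc(exp.atom_values, set(truth))
            except UndefinedAUCError:
                auc = None
        merged_ids = sorted({merge_map.get(a, a) for a, _ in mol.alert_hits})
        rows.append(
            {
                "compound_id": exp.compound_id,
                "actual": actual,
                "predicted": predicted,
                "cell": cell,
                "attribution_auc": auc,
                "alert_ids": ";".join(merged_ids),
                "n_alerts": len(merged_ids),
            }
        )
    compound_df = pd.DataFrame(
        rows,
        columns=[
            "compound_id",
            "actual",
            "predicted",
            "cell",
            "attribution_auc",
            "alert_ids",
            "n_alerts",
        ],
    )
    tp = compound_df[(compound_df.cell == "TP") & compound_df.attribution_auc.notna()]
    if tp.empty:
        import warnings

        warnings.warn("no scorable TP compounds; evaluation tables are empty")
        alert_df = pd.DataFrame(columns=["alert_id", "n", "mean_auc"])
        summary = {
            "n_tp": 0,
            "median_auc": float("nan"),
            "fraction_auc_ge_0.8": float("nan"),
            "median_alert_auc": float("nan"),
            "fraction_alert_auc_ge_0.8": float("nan"),
        }
        return compound_df, alert_df, summary
    single = tp[tp.n_alerts == 1]
    alert_df = (
        single.groupby("alert_ids")["attribution_auc"]
        .agg(n="size", mean_auc="mean")
        .reset_index()
        .rename(columns={"alert_ids": "alert_id"})
    )
    aucs = tp.attribution_auc.to_numpy(dtype=float)
    summary = {
        "n_tp": int(len(tp)),
        "median_auc": float(np.median(aucs)),
        "fraction_auc_ge_0.8": float(np.mean(aucs >= 0.8)),
        "median_alert_auc": float(alert_df.mean_auc.median()) if len(alert_df) else float("nan"),
        "fraction_alert_auc_ge_0.8": (
            float((alert_df.mean_auc >= 0.8).mean()) if len(alert_df) else float("nan")
        ),
    }
    return compound_df, alert_df, summary


# ---------------------------------------------------------------------------
# Neuron diagnostics
# ---------------------------------------------------------------------------


@dataclass
class CorrelationReport:
    groups: dict[str, np.ndarray]  # group name -> flat array of pairwise correlations
    n_zero_variance: dict[int, int]  # layer -> number of constant neurons skipped


def _activation_matrix(model: TrainedModel, X: np.ndarray, layer: int) -> np.ndarray:
    return model.forward(X)["act"][layer]


def neuron_correlations(model: TrainedModel, compounds) -> CorrelationReport:
    """Pairwise Pearson correlations of neuron activations over compounds.

    Groups: within the first hidden layer, between first and second, within
    the second (two-layer models).  Self-pairs are excluded; zero-variance
    neurons are skipped and counted.
    """
    from .network import _as_matrix

    X = _as_matrix(compounds)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 compounds for correlations")
    n_hidden = model.n_layers - 1
    acts, keep, dropped = {}, {}, {}
    for layer in range(1, n_hidden + 1):
        A = _activation_matrix(model, X, layer)
        var = A.var(axis=0)
        keep[layer] = np.flatnonzero(var > 0)
        dropped[layer] = int((var == 0).sum())
        acts[layer] = A[:, keep[layer]]
    groups: dict[str, np.ndarray] = {}
    c1 = np.corrcoef(acts[1], rowvar=False)
    iu = np.triu_indices(c1.shape[0], k=1)
    groups["within-layer-1"] = c1[iu]
    if n_hidden == 2:
        both = np.corrcoef(np.hstack([acts[1], acts[2]]), rowvar=False)
        n1 = acts[1].shape[1]
        groups["between-1-and-2"] = both[:n1, n1:].ravel()
        c2 = both[n1:, n1:]
        iu2 = np.triu_indices(c2.shape[0], k=1)
        groups["within-layer-2"] = c2[iu2]
    return CorrelationReport(groups=groups, n_zero_variance=dropped)


def neuron_classifier_auc(
    activations: Sequence[float] | np.ndarray, labels: Sequence[int] | np.ndarray
) -> float:
    """ROC-AUC of a neuron's activation used as a classifier score."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise UndefinedAUCError("single-class labels")
    return float(roc_auc_score(y, np.asarray(activations, dtype=float)))
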