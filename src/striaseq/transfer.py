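"""Cross-stage transfer of response-type labels.

A random forest trained on the extended-stage taxonomy (phase features as
predictors, Start/Stop/Middle or EXC/INH as labels, one model per level-1
class) assigns subtype labels to early-stage units, which are first split
into Phasic/Non-phasic by the same Fourier procedure. Per-session class
proportions by region feed chi-squared contingency tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .config import AnalysisConfig
from .stats_report import chi_square

PHASE_FEATURE_COLS = ["init_mean", "exec_mean", "term_mean"]


@dataclass
class ReferenceModel:
    model: RandomForestClassifier
    oob_error: float
    classes: list[str]


def train_reference(
    features: np.ndarray,
    labels: Sequence[str],
    n_trees: int = 500,
    seed: int = 0,
) -> ReferenceModel:
    """Fit the reference forest and report its out-of-bag error."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.shape[0] < 20:
        raise ValueError("need at least 20 labeled units to train a reference model")
    if len(np.unique(labels)) < 2:
        raise ValueError("single-class input: nothing to learn")
    model = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed
    )
    model.fit(features, labels)
    return ReferenceModel(
        model=model,
        oob_error=float(1.0 - model.oob_score_),
        classes=list(model.classes_),
    )


def apply_transfer(ref: ReferenceModel, early_features: np.ndarray) -> np.ndarray:
    """Label early-stage units with the reference model."""
    early_features = np.asarray(early_features, dtype=float)
    if early_features.size == 0:
        return np.array([], dtype=object)
    if early_features.shape[1] != ref.model.n_features_in_:
        raise ValueError(
            f"feature dimension {early_features.shape[1]} != "
            f"{ref.model.n_features_in_} used in training"
        )
    labels = ref.model.predict(early_features)
    if len(set(labels)) == 1 and len(labels) > 1:
        import warnings

        warnings.warn("transfer produced a single class for every unit", stacklevel=2)
    return labels


def transfer_sessions(
    extended_table: pd.DataFrame,
    early_tables: dict,
    seed: int = 0,
) -> pd.DataFrame:
    """Train on the extended taxonomy table and label each early session.

    ``early_tables`` maps session_id to a taxonomy-style table whose
    ``level1`` column comes from the session's own Fourier split; the
    returned frame adds the transferred ``level2`` labels.
    """
    models = {}
    for group in ("Phasic", "Non-phasic"):
        sub = extended_table[extended_table["level1"] == group]
        if sub["level2"].nunique() >= 2 and len(sub) >= 20:
            models[group] = train_reference(
                sub[PHASE_FEATURE_COLS].to_numpy(), sub["level2"], seed=seed
            )
    out = []
    for sid, table in early_tables.items():
        table = table.copy()
        table["session_id"] = sid
        table["level2"] = ""
        for group, ref in models.items():
            idx = table.index[table["level1"] == group]
            if len(idx):
                table.loc[idx, "level2"] = apply_transfer(
                    ref, table.loc[idx, PHASE_FEATURE_COLS].to_numpy()
                )
        out.append(table)
    return pd.concat(out, ignore_index=True)


def proportion_tables(labeled: pd.DataFrame, level: str = "level2") -> pd.DataFrame:
    """Per-session region x class contingency tables with chi-squared stats.

    Returns one row per (session, level-1 group) with the counts, the class
    proportions per region, and the Pearson chi-squared test of homogeneity.
    """
    rows = []
    for (sid, group), sub in labeled.groupby(["session_id", "level1"]):
        counts = pd.crosstab(sub["region"], sub[level])
        counts = counts.loc[:, counts.sum(axis=0) > 0]
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            import warnings

            warnings.warn(
                f"{sid}/{group}: degenerate contingency table, skipped", stacklevel=2
            )
            continue
        stat, df, p = chi_square(counts.to_numpy())
        props = counts.div(counts.sum(axis=1), axis=0)
        rows.append(
            {
                "session_id": sid,
                "level1": group,
                "table": counts.to_dict(),
                "proportions": props.to_dict(),
                "chi2": stat,
                "df": df,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
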