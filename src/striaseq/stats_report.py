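"""Contingency statistics and the end-to-end pipeline driver."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on an R x C count table.

    No continuity correction; statistic = sum (O - E)^2 / E with expected
    counts from the product of the margins, df = (R-1)(C-1).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: expected counts undefined")
    res = chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def run_pipeline(
    sessions,
    extended,
    out_dir: str | Path,
    config=None,
    seed: int = 0,
) -> dict:
    """Run screening, peri-event normalization, taxonomy, transfer, decoding
    and correlation on a set of early sessions plus an extended cohort, and
    write the result tables under ``out_dir``.

    Returns a manifest dict naming every artifact written; stage failures
    leave the partial outputs in place and are recorded in the manifest.
    """
    from . import correlation, decoding, psth, response_typing, transfer, units
    from .config import AnalysisConfig

    config = config or AnalysisConfig(seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": {}, "failures": {}, "seed": seed}

    def _stage(name, fn):
        try:
            fn()
        except Exception as e:  # retain partial outputs, record the failure
            manifest["failures"][name] = f"{type(e).__name__}: {e}"

    state: dict = {}

    def screen():
        for s in list(sessions) + [extended]:
            units.screen_session(s, config)
        state["pems"] = {}
        for s in list(sessions) + [extended]:
            pems = []
            for u in units.msns(s.units):
                pem = psth.peri_event_matrix(u, s, config)
                if pem is not None and units.baseline_filter(u, config):
                    pems.append(pem)
            state["pems"][s.session_id] = pems

    def taxonomy():
        tax = response_typing.classify_taxonomy(
            state["pems"][extended.session_id], config,
            rng=np.random.default_rng(seed), n_perm=min(config.n_perm, 200),
        )
        state["taxonomy"] = tax
        tax.table.to_csv(out_dir / "taxonomy.csv", index=False)
        sidecar = {
            "level1": {"selected_k": tax.level1.selected_k,
                       "ch": tax.level1.ch_values, "p": tax.level1.p_value},
            "level2": {g: {"selected_k": r.selected_k, "ch": r.ch_values,
                           "p": r.p_value} for g, r in tax.level2.items()},
        }
        (out_dir / "taxonomy_ch.json").write_text(json.dumps(sidecar, indent=1))
        manifest["outputs"]["taxonomy"] = "taxonomy.csv"

    def do_transfer():
        early_tables = {}
        for s in sessions:
            pems = state["pems"][s.session_id]
            if len(pems) <= max(config.k_list):
                continue
            tab = response_typing.classify_taxonomy(
                pems, config, rng=np.random.default_rng(seed), n_perm=100
            ).table
            early_tables[s.session_id] = tab
        labeled = transfer.transfer_sessions(
            state["taxonomy"].table, early_tables, seed=seed
        )
        labeled.to_csv(out_dir / "early_labels.csv", index=False)
        props = transfer.proportion_tables(labeled)
        props.to_csv(out_dir / "chi_square.csv", index=False)
        manifest["outputs"]["early_labels"] = "early_labels.csv"
        manifest["outputs"]["chi_square"] = "chi_square.csv"

    def decode():
        rows = []
        for s in sessions:
            if s.stage != "DT5_early":
                continue
            pems = state["pems"][s.session_id]
            feats = decoding.feature_matrix(pems, config)
            regions = np.array([p.region for p in pems])
            if min((regions == "DLS").sum(), (regions == "DMS").sum()) < config.n_folds:
                continue
            res = decoding.decode_region(feats, regions, config, seed=seed)
            rows.append(
                {"context": s.session_id, "mean_true": res.true_accuracies.mean(),
                 "mean_shuffled": res.shuffled_accuracies.mean(), "p": res.p_value}
            )
        ext_pems = state["pems"][extended.session_id]
        feats = decoding.feature_matrix(ext_pems, config)
        regions = np.array([p.region for p in ext_pems])
        for res in decoding.ensemble_sweep(feats, regions, config, seed=seed):
            rows.append(
                {"context": f"ensemble_{res.context}",
                 "mean_true": res.true_accuracies.mean(),
                 "mean_shuffled": res.shuffled_accuracies.mean(), "p": res.p_value}
            )
        pd.DataFrame(rows).to_csv(out_dir / "decoding.csv", index=False)
        manifest["outputs"]["decoding"] = "decoding.csv"

    def correlate():
        recs = correlation.cohort_correlations(
            extended, state["pems"][extended.session_id], config
        )
        recs.to_csv(out_dir / "correlations.csv", index=False)
        manifest["outputs"]["correlations"] = "correlations.csv"

    _stage("screen", screen)
    if "pems" in state:
        _stage("taxonomy", taxonomy)
        if "taxonomy" in state:
            _stage("transfer", do_transfer)
        _stage("decoding", decode)
        _stage("correlation", correlate)
    else:
        manifest["failures"].setdefault("screen", "no peri-event matrices computed")

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
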