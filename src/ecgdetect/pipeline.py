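"""End-to-end pipeline runs and reporting.

One *cell* of the results table is a combination (DR method x selector x
classifier family x tuner) evaluated on one disease pair (VT, PVC or ST
against NSR).  A run executes: simulate -> decimate -> embed (per class,
since arrhythmia and NSR epochs differ in length and sampling rate) ->
select -> optionally tune -> train and evaluate by stratified K-fold
cross-validation.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ecgdetect import classifiers as clf
from ecgdetect import tuning
from ecgdetect.embedding import DMParams, LEParams, LLEParams, decimate_epochs, embed
from ecgdetect.epochs import SyntheticConfig, generate_synthetic_ecg
from ecgdetect.evaluation import evaluate_classifier
from ecgdetect.selection import (
    CuckooConfig,
    HarmonyConfig,
    select_epochs,
)

#: post-selection retention per class, mirroring the ~15-20% kept by the
#: reference pipeline (333/2167, 444/2889, 778/4200, 1406/7088)
SELECT_FRACTION = {"VT": 333 / 2167, "PVC": 444 / 2889,
                   "ST": 778 / 4200, "NSR": 1406 / 7088}

PAIRS = ("VT", "PVC", "ST")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (possibly many table cells).

    n_epochs is the pre-decimation epoch count per class; embed_dim the
    embedding dimensionality; selector/tuner entries may be "none".
    Optimizer budgets are deliberately small defaults suited to the
    synthetic problem sizes; raise them for larger studies.
    """

    pair: str = "VT"
    dr_methods: tuple[str, ...] = ("lle",)
    selectors: tuple[str, ...] = ("none",)
    families: tuple[str, ...] = ("gmm",)
    tuners: tuple[str, ...] = ("none",)
    n_epochs: int = 2000
    embed_dim: int = 8
    k_neighbors: int = 12
    folds: int = 10
    seed: int = 0
    noise_sd: float = 0.05
    artifact_frac: float = 0.15
    select_fraction: dict = field(default_factory=lambda: dict(SELECT_FRACTION))
    selector_budget: int = 60      # optimizer iterations/improvisations
    gso_points: int = 3
    adam_iterations: int = 20
    tuning_folds: int = 5
    out_dir: str | None = None
    dfa_on_raw: bool = True
    classifier_configs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pair not in PAIRS:
            raise ValueError(f"pair must be one of {PAIRS}, got {self.pair!r}")
        known = {"none", "cs", "hso"}
        bad = {s.lower() for s in self.selectors} - known
        if bad:
            raise ValueError(f"unknown selectors {bad}")
        bad = {t.lower() for t in self.tuners} - {"none", "gso", "adam"}
        if bad:
            raise ValueError(f"unknown tuners {bad}")


@dataclass
class ResultsTable:
    rows: pd.DataFrame

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "ResultsTable":
        return ResultsTable(pd.read_csv(path))


def _default_family_config(family: str, seed: int):
    if family == "firefly":
        return clf.FireflyConfig(population=20, max_iter=40, seed=seed)
    if family == "gmm":
        return clf.GMMConfig(seed=seed)
    return clf.DEFAULT_CONFIGS[family]()


def _simulate_pair(config: RunConfig):
    mats = {}
    for i, lab in enumerate((config.pair, "NSR")):
        mats[lab] = generate_synthetic_ecg(
            SyntheticConfig(
                class_label=lab,
                n_epochs=config.n_epochs,
                seed=config.seed * 1009 + i,
                noise_sd=config.noise_sd,
                artifact_frac=config.artifact_frac,
            )
        )
    return mats


def _embed_classes(mats, method, config: RunConfig):
    """Embed each class separately (epoch lengths differ across classes)
    and stack coordinates; returns (coords, labels01, raw_rows)."""
    coords, labels, raws = [], [], []
    for lab, mat in mats.items():
        dec = decimate_epochs(mat)
        if method == "lle":
            params = LLEParams(k_neighbors=config.k_neighbors,
                               target_dim=config.embed_dim)
        elif method == "dm":
            params = DMParams(h=config.embed_dim)
        else:
            params = LEParams(m_neighbors=config.k_neighbors,
                              target_dim=config.embed_dim)
        res = embed(dec, method, params)
        coords.append(res.coords)
        labels.extend([1 if lab != "NSR" else 0] * res.coords.shape[0])
        raws.append(dec.data)
    return np.vstack(coords), np.array(labels), raws


class StageError(RuntimeError):
    def __init__(self, stage: str, artifact: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed on {artifact}: {cause}")
        self.stage, self.artifact = stage, artifact


def run_pipeline(config: RunConfig) -> ResultsTable:
    """Execute every (DR x selector x family x tuner) cell of the config.

    Deterministic given the config (one global seed drives simulation,
    optimizers, folds and initialization); writes intermediate CSVs and
    a config snapshot when ``out_dir`` is set.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(json.dumps(_jsonable(config), indent=2))

    t0 = time.time()
    try:
        mats = _simulate_pair(config)
    except Exception as e:  # pragma: no cover - config validation upstream
        raise StageError("simulate", config.pair, e)

    rows = []
    for method in config.dr_methods:
        try:
            coords, labels01, raws = _embed_classes(mats, method.lower(), config)
        except Exception as e:
            raise StageError("embed", method, e)
        # raw epochs for the DFA classifier; classes with differing epoch
        # lengths are truncated to the common minimum so every row is a
        # comparable time series
        minlen = min(r.shape[1] for r in raws)
        raw_concat = np.vstack([r[:, :minlen] for r in raws])
        if out:
            pd.DataFrame(coords).assign(label=labels01).to_csv(
                out / f"embedding_{method}.csv", index=False
            )
        for selector in config.selectors:
            sel_key = selector.lower()
            if sel_key == "none":
                kept = np.arange(len(labels01))
            else:
                targets = _selection_targets(labels01, config)
                emb = _CoordsView(coords, labels01)
                opt_cfg = (
                    CuckooConfig(max_iter=config.selector_budget,
                                 seed=config.seed + 17)
                    if sel_key == "cs"
                    else HarmonyConfig(Vmax=config.selector_budget * 25,
                                       seed=config.seed + 17)
                )
                try:
                    sel = select_epochs(emb, labels01, sel_key.upper()
                                        if sel_key != "hso" else "HSO",
                                        targets, opt_cfg)
                except Exception as e:
                    raise StageError("select", f"{method}/{selector}", e)
                kept = sel.kept_ids
            x_sel, y_sel = coords[kept], labels01[kept]
            for family in config.families:
                feats = x_sel
                if family == "dfa" and config.dfa_on_raw and raw_concat is not None:
                    feats = raw_concat[kept]
                for tuner in config.tuners:
                    cell = dict(dr=method.upper(), selector=selector.upper(),
                                classifier=family, tuner=tuner,
                                pair=f"{config.pair}-vs-NSR")
                    try:
                        rec = _evaluate_cell(
                            family, tuner.lower(), feats, y_sel, config
                        )
                    except Exception as e:
                        raise StageError(
                            "evaluate", "/".join(map(str, cell.values())), e
                        )
                    rows.append({**cell, **rec.as_dict()})
    table = ResultsTable(pd.DataFrame(rows))
    if out:
        table.to_csv(out / "results.csv")
        (out / "run.log").write_text(
            f"cells={len(rows)} wall_time_s={time.time() - t0:.1f} "
            f"seed={config.seed}\n"
        )
    return table


def _selection_targets(labels01, config: RunConfig):
    pos_frac = config.select_fraction.get(config.pair, 0.16)
    neg_frac = config.select_fraction.get("NSR", 0.2)
    n_pos = int(np.sum(labels01 == 1))
    n_neg = int(np.sum(labels01 == 0))
    return {
        1: max(int(round(pos_frac * n_pos)), min(config.folds, n_pos)),
        0: max(int(round(neg_frac * n_neg)), min(config.folds, n_neg)),
    }


class _CoordsView:
    """Minimal embedding view for the selector (coords + labels)."""

    def __init__(self, coords, labels):
        self.coords = coords
        self.labels = labels


def _evaluate_cell(family, tuner, feats, y, config: RunConfig):
    base = config.classifier_configs.get(
        family, _default_family_config(family, config.seed)
    )
    cfg = base
    if tuner != "none" and family in tuning.TUNABLE:
        names = tuning.TUNABLE[family]
        if tuner == "gso":
            spec = tuning.GridSpec(names=names, points=config.gso_points,
                                   cv_folds=config.tuning_folds)
            best, _ = tuning.grid_search(
                family, spec, feats, y, seed=config.seed + 29, base_config=base
            )
        else:
            best, _, _ = tuning.adam_tune(
                family, feats, y,
                init=np.full(len(names), 0.5),
                max_iter=config.adam_iterations,
                cv_folds=config.tuning_folds,
                seed=config.seed + 29,
                base_config=base,
            )
        from dataclasses import replace

        cfg = replace(base, **best)
    # final metrics use a fresh fold seed, distinct from the tuning folds
    return evaluate_classifier(
        lambda x_, y_: clf.fit(x_, y_, family, cfg),
        feats, y, K=config.folds, seed=config.seed + 101,
    ).metrics


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def report(table: ResultsTable, out_path, fmt: str = "csv") -> None:
    """Write a results table; 'csv' always, 'text' adds a grouped
    per-DR-technique rendering."""
    if table.rows.empty:
        raise ValueError("refusing to report an empty results table")
    out_path = Path(out_path)
    if fmt == "csv":
        table.to_csv(out_path)
        return
    if fmt == "text":
        lines = []
        for dr, group in table.rows.groupby("dr", sort=False):
            lines.append(f"== {dr} ==")
            lines.append(group.drop(columns="dr").to_string(index=False))
            lines.append("")
        out_path.write_text("\n".join(lines))
        return
    raise ValueError(f"unknown report format {fmt!r}")
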