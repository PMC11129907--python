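"""End-to-end orchestration: simulate -> windows -> features -> select ->
rebalance -> train -> dual evaluation.

``run_pipeline`` reproduces the whole analysis on synthetic sessions so
every stage can be exercised, timed and regression-tested without the
clinical recordings. The default benchmark simulates 24 subjects (one
monitored limb each, ~2 h 48 min per session at 50 Hz) — the study-scale
number of patients — and carries the windows through the 90-feature
extraction, MI top-30 selection, 300/300/300 rebalancing, a 75/25 split
and SVM-RBF evaluation on both the held-out split and the discarded pool.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as ft
from . import io as tkio
from . import model_eval as me
from . import rebalance as rb
from .synth import LIMBS, SessionConfig, simulate_session

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, with study-scale defaults."""

    session: SessionConfig = field(default_factory=SessionConfig)
    n_sessions: int = 24
    top_k: int = 30
    target: int = rb.DEFAULT_TARGET
    smote_k: int = rb.DEFAULT_SMOTE_K
    train_frac: float = 0.75
    svm_C: float = 1.0
    svm_gamma: float | str = "scale"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sess = d.pop("session", {})
        if isinstance(sess, dict):
            sess = SessionConfig(**sess)
        return cls(session=sess, **d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    """Artifacts of one end-to-end run."""

    config: PipelineConfig
    seed: int
    n_windows: int
    class_counts: dict[int, int]
    ranking: pd.DataFrame
    selected: list[str]
    dataset: rb.ResampledDataset
    model: me.TrainedModel
    report_test: me.EvalReport
    report_discarded: me.EvalReport
    pca_initial: np.ndarray
    pca_resampled: np.ndarray
    labels_initial: np.ndarray

    def summary(self) -> dict:
        n_syn = int(self.dataset.synthetic.sum())
        return {
            "seed": self.seed,
            "n_sessions": self.config.n_sessions,
            "n_windows": self.n_windows,
            "class_counts": {int(k): int(v) for k, v in self.class_counts.items()},
            "n_selected_features": len(self.selected),
            "balanced_rows": int(len(self.dataset.X)),
            "synthetic_rows": n_syn,
            "synthetic_fraction": n_syn / len(self.dataset.X),
            "discarded_rows": int(len(self.dataset.discarded_X)),
            "test": self.report_test.to_dict(),
            "discarded": self.report_discarded.to_dict(),
        }

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as f:
            json.dump(self.summary(), f, indent=2)
        self.ranking.to_csv(out / "mi_ranking.csv", index=False)
        for rep in (self.report_test, self.report_discarded):
            pd.DataFrame(rep.confusion, index=me.CLASSES, columns=me.CLASSES).to_csv(
                out / f"confusion_{rep.dataset_id}.csv"
            )
        coords = pd.DataFrame(self.pca_resampled, columns=["pc1", "pc2"])
        coords["label"] = self.dataset.y
        coords["synthetic"] = self.dataset.synthetic
        coords.to_csv(out / "pca_resampled.csv", index=False)


def simulate_cohort(config: PipelineConfig, seed: int) -> list[tkio.LabelledWindow]:
    """Simulate ``n_sessions`` labelled sessions and pool their windows.

    Each session gets an independent subject id, a limb cycling through
    the four sensor sites, and a sub-seed derived from ``seed``; windows
    stay limb-matched to their labels by construction.
    """
    ss = np.random.SeedSequence(seed)
    windows: list[tkio.LabelledWindow] = []
    for i, child in enumerate(ss.spawn(config.n_sessions)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        scfg = config.session.replace(seed=sub_seed)
        limb = LIMBS[i % len(LIMBS)]
        rec, events = simulate_session(scfg, subject_id=f"S{i:02d}", limb=limb)
        windows.extend(tkio.extract_windows(rec, events))
    return windows


def run_pipeline(config: PipelineConfig | None = None, seed: int = 0) -> PipelineResult:
    """Run the full analysis on a simulated cohort and return all artifacts."""
    config = config or PipelineConfig()
    windows = simulate_cohort(config, seed)
    labels = np.array([w.label for w in windows])
    counts = {c: int(np.sum(labels == c)) for c in (0, 1, 2)}
    logger.info("cohort: %d windows, class counts %s", len(windows), counts)

    fm = ft.extract_features(windows)
    ranking = ft.mutual_information_ranking(fm, base_seed=seed)
    selected = ft.select_top_k(ranking, k=config.top_k)
    fm_sel = fm[selected + [ft.LABEL_COLUMN]]

    ds = rb.rebalance_dataset(fm_sel, target=config.target, k=config.smote_k, seed=seed)
    train, test = me.train_test_split(ds, train_frac=config.train_frac, seed=seed)
    model = me.train_svm(train, C=config.svm_C, gamma=config.svm_gamma, seed=seed)
    report_test = me.evaluate(model, *test, dataset_id="in_sample_test")
    report_discarded = me.evaluate_discarded(model, ds)

    X_initial = fm[selected]
    pca_initial = me.pca_embedding(X_initial)
    pca_resampled = me.pca_embedding(ds.X, fit_on=X_initial)

    return PipelineResult(
        config=config,
        seed=seed,
        n_windows=len(windows),
        class_counts=counts,
        ranking=ranking,
        selected=selected,
        dataset=ds,
        model=model,
        report_test=report_test,
        report_discarded=report_discarded,
        pca_initial=pca_initial,
        pca_resampled=pca_resampled,
        labels_initial=labels,
    )
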