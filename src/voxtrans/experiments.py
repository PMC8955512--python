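"""Scaled-down experiment runners: the augmentation on/off ablation.

Trains the same model twice on the same data and seed — once without
rotation augmentation, once with it — recording mean MSSIM against the
training and held-out pairs every ``eval_every`` iterations, and reports
the paired curves.  The expectation at full scale is that the
no-augmentation run overfits: its train-test MSSIM gap at the end exceeds
the augmented run's.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from .augmentation import RotationSchedule
from .gan3d import GeneratorConfig, train_model
from .patching import PatchLayout, extract_patch
from .preprocess import PairedSample

__all__ = ["AblationReport", "run_ablation"]


@dataclass
class AblationReport:
    """Histories of the two experiments plus the final train-test gaps."""

    history_no_aug: list = field(default_factory=list)
    history_aug: list = field(default_factory=list)

    @staticmethod
    def _final_gap(history) -> float:
        last = history[-1]
        return float(last["train_mssim"] - last["test_mssim"])

    @property
    def final_gap_no_aug(self) -> float:
        return self._final_gap(self.history_no_aug)

    @property
    def final_gap_aug(self) -> float:
        return self._final_gap(self.history_aug)

    def write_csv(self, path) -> None:
        keys = ["iteration", "epoch", "loss_D", "loss_G", "train_mssim", "test_mssim"]
        with open(path, "w", newline="") as f:
            writer = csv.writer(f)
            writer.writerow(["experiment"] + keys)
            for name, hist in (("no_aug", self.history_no_aug),
                               ("aug", self.history_aug)):
                for rec in hist:
                    writer.writerow([name] + [rec.get(k, "") for k in keys])

    def plot(self, path) -> None:  # pragma: no cover - cosmetic output
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, hist, title in ((axes[0], self.history_no_aug, "Experiment 1: no augmentation"),
                                (axes[1], self.history_aug, "Experiment 2: augmented")):
            its = [r["iteration"] for r in hist]
            ax.plot(its, [r["train_mssim"] for r in hist], label="train")
            ax.plot(its, [r["test_mssim"] for r in hist], label="test")
            ax.set_title(title)
            ax.set_xlabel("iteration")
            ax.set_ylabel("mean MSSIM")
            ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _patch_pairs(samples, layout: PatchLayout | None, patch_index: int):
    if layout is None:
        return list(samples)
    return [PairedSample(subject_id=s.subject_id,
                         mr=extract_patch(s.mr, layout, patch_index),
                         ct=extract_patch(s.ct, layout, patch_index))
            for s in samples]


def run_ablation(train_pairs, test_pairs, cfg: GeneratorConfig,
                 iterations: int, eval_every: int | None = None,
                 seed: int = 0, layout: PatchLayout | None = None,
                 patch_index: int = 3) -> AblationReport:
    """Train the same model with augmentation off (experiment 1) then on
    (experiment 2); identical data, config, and seed otherwise.

    ``eval_every`` defaults to one evaluation per epoch (every
    ``len(train_pairs)`` iterations), matching the convention of validating
    after each pass over the training subjects.
    """
    train = _patch_pairs(train_pairs, layout, patch_index)
    test = _patch_pairs(test_pairs, layout, patch_index)
    if eval_every is None:
        eval_every = len(train)
    no_aug = train_model(train, cfg, iterations=iterations, schedule=None,
                         eval_every=eval_every, seed=seed, test_dataset=test)
    aug = train_model(train, cfg, iterations=iterations,
                      schedule=RotationSchedule(rng_seed=seed),
                      eval_every=eval_every, seed=seed, test_dataset=test)
    if len(no_aug.history) != len(aug.history):
        raise RuntimeError("ablation histories have unequal length")
    return AblationReport(history_no_aug=no_aug.history, history_aug=aug.history)
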