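"""Model/Results front end for the GP+KNN spike detector.

`SpikeDetector` is constructed from class-balanced reference and
validation feature groups (or from per-patient labeled feature tables via
`from_feature_tables`).  `fit()` runs the genetic-programming search for
the discriminative scalar formula and returns `SpikeDetectorResults`,
which carries the evolved formula, its validation error, the fitness
trace, and the frozen KNN reference model; detection on new recordings
and sensitivity/specificity evaluation hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import gp as _gp
from .detect import (
    ConfusionCounts,
    RegionalDecision,
    detect as _run_detect,
    evaluate as _evaluate_decisions,
)
from .knn import KNNModel
from .preprocess import FEATURE_NAMES, Recording, SegmentationConfig


class SpikeDetector:
    """Patient-independent interictal spike detector.

    Parameters
    ----------
    reference_features, reference_labels
        Class-balanced feature group whose formula outputs become the KNN
        reference points.
    validation_features, validation_labels
        Held-out balanced group on which candidate formulas are scored
        (the GP wrapper fitness is the KNN error rate here).
    seg_cfg
        Windowing used when the fitted detector is applied to recordings.
    gp_config
        Evolution parameters; defaults follow the published settings
        (population 25, 100 generations, depth limit 25, adaptive
        crossover/mutation probabilities starting at 0.90/0.10).
    knn_k
        Neighbor count for both the fitness wrapper and the final
        classifier (clamped to the reference-set size).
    """

    def __init__(self, reference_features, reference_labels,
                 validation_features, validation_labels,
                 seg_cfg: SegmentationConfig | None = None,
                 gp_config: _gp.GPConfig | None = None,
                 knn_k: int = 100):
        self.seg_cfg = seg_cfg or SegmentationConfig()
        self.gp_config = gp_config or _gp.GPConfig()
        self.knn_k = knn_k
        self.ctx = _gp.FitnessContext(
            reference_features=reference_features,
            reference_labels=reference_labels,
            validation_features=validation_features,
            validation_labels=validation_labels,
            k=min(knn_k, np.asarray(reference_labels).size),
        )

    @classmethod
    def from_feature_tables(cls, tables: Sequence[pd.DataFrame],
                            n_reference: int = 4, n_validation: int = 4,
                            balance_seed: int = 0,
                            max_per_class: int | None = 200,
                            **kwargs) -> "SpikeDetector":
        """Build groups from per-patient labeled feature tables.

        Patients (not segments) are split into reference and validation
        groups; see `spikegp.pipeline.build_groups` for the balancing
        rules.
        """
        from .pipeline import build_groups

        ctx, _assignment = build_groups(
            tables, n_reference=n_reference, n_validation=n_validation,
            balance_seed=balance_seed, max_per_class=max_per_class,
            k=kwargs.get("knn_k", 100))
        return cls(ctx.reference_features, ctx.reference_labels,
                   ctx.validation_features, ctx.validation_labels, **kwargs)

    def fit(self, seed: int | None = None) -> "SpikeDetectorResults":
        """Evolve the formula and freeze the KNN reference model."""
        cfg = self.gp_config
        if seed is not None:
            from dataclasses import replace
            cfg = replace(cfg, rng_seed=seed)
        evo = _gp.evolve(self.ctx, cfg)
        ref_scalars = np.atleast_1d(
            _gp.evaluate_formula(evo.best_tree, self.ctx.reference_features))
        knn = KNNModel(ref_scalars, self.ctx.reference_labels, k=self.ctx.k)
        return SpikeDetectorResults(model=self, formula=evo.best_tree,
                                    validation_error=evo.best_fitness,
                                    trace=evo.trace, knn=knn)


@dataclass
class SpikeDetectorResults:
    """Fitted detector: evolved formula plus frozen KNN references."""

    model: SpikeDetector
    formula: _gp.Tree
    validation_error: float
    trace: np.ndarray
    knn: KNNModel

    @property
    def formula_sexp(self) -> str:
        return _gp.to_sexp(self.formula)

    def detect(self, recording: Recording,
               annotations: Sequence[tuple[int, int]] | None = None,
               ) -> list[RegionalDecision]:
        return _run_detect(recording, self.formula, self.knn,
                           self.model.seg_cfg, annotations)

    def evaluate(self, recordings_with_annotations: Sequence[
            tuple[Recording, Sequence[tuple[int, int]]]],
            ) -> tuple[float | None, float | None, ConfusionCounts]:
        """Pooled sensitivity/specificity over held-out recordings."""
        decisions: list[RegionalDecision] = []
        for recording, events in recordings_with_annotations:
            decisions.extend(self.detect(recording, events))
        return _evaluate_decisions(decisions)

    def used_features(self) -> list[str]:
        """Feature names appearing as terminals of the evolved formula."""
        found: set[int] = set()

        def walk(node: _gp.Tree) -> None:
            if _gp.is_terminal(node):
                found.add(node[1])
            else:
                for child in node[1:]:
                    walk(child)

        walk(self.formula)
        return [FEATURE_NAMES[i - 1] for i in sorted(found)]

    def summary(self) -> str:
        ctx = self.model.ctx
        lines = [
            "GP+KNN spike detector results",
            "=" * 46,
            f"{'evolved formula':<28}{self.formula_sexp}",
            f"{'features used':<28}{', '.join(self.used_features())}",
            f"{'validation error rate':<28}{self.validation_error:.4f}",
            f"{'generations':<28}{self.trace.size}",
            f"{'initial best error':<28}{self.trace[0]:.4f}",
            f"{'reference points':<28}{ctx.reference_labels.size}"
            f" ({int(ctx.reference_labels.sum())} spike)",
            f"{'validation segments':<28}{ctx.validation_labels.size}",
            f"{'KNN neighbors (k)':<28}{self.knn.k}",
            "=" * 46,
        ]
        return "\n".join(lines)
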