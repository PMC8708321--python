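"""End-to-end orchestration: curation counts, headline scores, synthetic runs.

``replication_counts`` and ``headline_scores`` reproduce the published
analysis when the user supplies the curated BBBP-schema files (they are not
bundled).  ``run_synthetic_pipeline`` exercises every stage on generated
data and is what the acceptance script executes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import data_io, descriptors, evaluation_report, models, scaffold_split, search_ensemble
from .synthetic_data import GeneratorConfig, generate


def replication_counts(intact_csv: str | Path, patches_csv: str | Path | None = None) -> dict:
    """Curation and split counts for a user-supplied intact BBBP dataset.

    Returns the intact record count, the independent-item count after
    free-form curation, the fixed-split sizes, and the multi-member-group /
    singleton decomposition of the training partition.
    """
    records = data_io.read_bbbp_csv(intact_csv)
    patches = data_io.read_patch_csv(patches_csv) if patches_csv else None
    curated, report = data_io.curate_free_form(records, patches)
    split = scaffold_split.fixed_scaffold_split(curated)
    groups = scaffold_split.group_by_scaffold(curated)
    singles = {g.member_indices[0] for g in groups if len(g.member_indices) == 1}
    multi_train = [i for i in split.train if i not in singles]
    single_train = [i for i in split.train if i in singles]
    return {
        "n_intact": len(records),
        "n_independent": len(curated),
        "n_removed": len(report.removed_nums),
        "split": (len(split.train), len(split.valid), len(split.test)),
        "n_train_multi_member": len(multi_train),
        "n_train_singleton": len(single_train),
        "n_singleton_pool": len(single_train) + len(split.valid) + len(split.test),
    }


def headline_scores(
    free_form_csv: str | Path,
    n_trials: int = 5,
    base_seed: int = 0,
) -> dict:
    """Soft regression check: RF/Large212 and DNN/FreeV11 on a curated dataset."""
    records = data_io.read_bbbp_csv(free_form_csv)
    labels = [r.p_np for r in records]
    split = scaffold_split.fixed_scaffold_split(records)
    panel = descriptors.compute_panel(records)

    large212 = descriptors.select_set(panel, "Large212")
    rf = models.run_trials(models.RF_CONFIG, large212.values, labels, split,
                           n_trials=n_trials, base_seed=base_seed)

    free11 = descriptors.max_normalize(
        descriptors.select_set(panel, "FreeV11"), reference_rows=split.train
    )
    dnn = models.run_trials(models.DNN_CONFIG, free11.values, labels, split,
                            n_trials=n_trials, base_seed=base_seed)
    return {
        "rf_large212": rf.summary(),
        "dnn_freev11": dnn.summary(),
    }


@dataclass
class SyntheticRunResult:
    n_generated: int
    n_curated: int
    split_sizes: tuple[int, int, int]
    rf: models.TrialResult
    dnn: models.TrialResult
    search_selected: list[str]
    ensemble_test_auc: float
    ci: evaluation_report.ConfidenceInterval


def run_synthetic_pipeline(
    seed: int = 0,
    n_molecules: int = 800,
    n_resamples: int = 25,
    n_trials: int = 3,
) -> SyntheticRunResult:
    """Run every pipeline stage on a generated dataset.

    Generation -> free-form curation -> descriptor panel -> fixed scaffold
    split -> RF and DNN trials -> a short forward search -> power-mean
    ensemble with clipping -> singleton-pool resampling with a t-interval on
    the RF test scores.
    """
    config = GeneratorConfig(n_molecules=n_molecules, seed=seed)
    raw = generate(config)
    curated, _ = data_io.curate_free_form(raw)
    labels = np.array([r.p_np for r in curated])
    split = scaffold_split.fixed_scaffold_split(curated)
    panel = descriptors.compute_panel(curated)

    large212 = descriptors.select_set(panel, "Large212")
    rf = models.run_trials(models.RF_CONFIG, large212.values, labels, split,
                           n_trials=n_trials, base_seed=seed)

    informative = descriptors.DescriptorMatrix(
        frame=panel.frame.loc[:, list(descriptors.FREE_V11)], set_name="FreeV11"
    )
    norm = descriptors.max_normalize(informative, reference_rows=split.train)
    dnn_cfg = models.ModelConfig(kind="dnn", units=64, epochs=40, seed=seed)
    dnn = models.run_trials(dnn_cfg, norm.values, labels, split,
                            n_trials=n_trials, base_seed=seed)

    search_cfg = models.ModelConfig(kind="rf", n_trees=30, seed=seed)
    state = search_ensemble.forward_search(
        norm, labels, split, criterion="validation", config=search_cfg,
        max_steps=4, repeats=1, base_seed=seed,
    )

    rf_probs, _ = models.train_predict(
        models.RF_CONFIG, large212.values[split.train], labels[split.train],
        large212.values[split.test], seed,
    )
    dnn_probs, _ = models.train_predict(
        dnn_cfg, norm.values[split.train], labels[split.train],
        norm.values[split.test], seed,
    )
    spec = search_ensemble.EnsembleSpec(members=[rf_probs, dnn_probs], clipping=True)
    ens_auc = models.roc_auc(labels[split.test], spec.combine())

    reference = scaffold_split.singleton_reference_split(curated)
    resamples = scaffold_split.singleton_pool_resample(
        curated, reference, n_resamples=n_resamples, seed=seed
    )
    scores = []
    for rs in resamples:
        probs, _ = models.train_predict(
            models.RF_CONFIG, large212.values[rs.train], labels[rs.train],
            large212.values[rs.test], seed,
        )
        scores.append(models.roc_auc(labels[rs.test], probs))
    ci = evaluation_report.confidence_interval(scores)

    return SyntheticRunResult(
        n_generated=len(raw),
        n_curated=len(curated),
        split_sizes=(len(split.train), len(split.valid), len(split.test)),
        rf=rf,
        dnn=dnn,
        search_selected=state.selected,
        ensemble_test_auc=ens_auc,
        ci=ci,
    )
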