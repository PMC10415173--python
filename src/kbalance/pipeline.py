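"""End-to-end orchestration: sequences -> profiles -> balance -> train ->
predict -> evaluate, plus parameter sweeps and cross-validation.

A pipeline run is a pure function of its inputs and resolved config: one
master seed is fanned out deterministically to the synthesis, split,
balancing, subsetting and training stages, so stages can be rerun in
isolation and whole runs reproduce byte-identically. Balancing is fit on
the training split only and never touches test data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import sequence_io
from .balancing import BalancerConfig, balance, summarize_diagnostics
from .classifiers import ClassifierSpec, predict, save_model, train
from .evaluation import EvaluationReport, macro_average_precision, tally
from .kmer_features import FeatureConfig, profile_matrix, write_profiles
from .synthetic_data import generate, preset_benchmark

__all__ = [
    "RunConfig",
    "fan_out_seeds",
    "run_pipeline",
    "sweep",
    "cross_validate",
    "balanced_vs_random_experiment",
    "k_sweep_experiment",
    "separated4_experiment",
]

logger = logging.getLogger(__name__)

_STAGES = ("synthesis", "split", "balance", "subset", "train")


def fan_out_seeds(master_seed: int) -> dict[str, int]:
    """Derive one independent sub-seed (< 2^31) per pipeline stage."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {stage: int(c.generate_state(1)[0]) & 0x7FFFFFFF
            for stage, c in zip(_STAGES, children)}


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run.

    Input is either a named synthetic preset (``preset`` + ``n_total``)
    or a FASTA file with a label TSV. ``balance_training=False`` trains
    on the full training split (the unbalanced baseline).
    """

    k: int = 3
    G: int = 10
    N: int = 800
    balance_training: bool = True
    classifier: ClassifierSpec = field(default_factory=lambda: ClassifierSpec("subspace_knn"))
    seed: int = 0
    test_fraction: float = 0.3
    rank: str | None = None
    preset: str | None = None
    n_total: int | None = None
    fasta: str | None = None
    labels: str | None = None
    init_fraction: float = 0.3
    escape_threshold: int = 10

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classifier"] = dataclasses.asdict(self.classifier)
        return d


def _load_dataset(config: RunConfig, seeds: dict[str, int]) -> sequence_io.LabeledDataset:
    if config.preset is not None:
        if config.n_total is None:
            raise ValueError("preset input requires n_total")
        return generate(preset_benchmark(config.preset, config.n_total,
                                         seed=seeds["synthesis"]))
    if config.fasta is None or config.labels is None:
        raise ValueError("config must name either a preset or fasta+labels inputs")
    records = sequence_io.read_fasta(config.fasta)
    label_map = sequence_io.read_labels(config.labels)
    return sequence_io.attach_labels(records, label_map, rank=config.rank)


def run_pipeline(config: RunConfig, dataset=None, outdir=None) -> EvaluationReport:
    """Run the full flow; optionally persist every artifact under ``outdir``."""
    seeds = fan_out_seeds(config.seed)
    if dataset is None:
        dataset = _load_dataset(config, seeds)
    logger.info("dataset: %d records, %d classes", len(dataset), len(dataset.classes))

    fc = FeatureConfig(k=config.k)
    X, kept = profile_matrix(dataset.records, fc)
    ids = np.array([dataset.records[i].id for i in kept])
    y = np.array([dataset.labels[i] for i in kept])
    logger.info("profiles: %d x %d (%d records dropped)", *X.shape, len(dataset) - len(kept))

    idx_train, idx_test = train_test_split(
        np.arange(len(y)), test_size=config.test_fraction,
        stratify=y, random_state=seeds["split"])
    X_train, y_train = X[idx_train], y[idx_train]
    X_test, y_test = X[idx_test], y[idx_test]

    result = None
    if config.balance_training:
        bcfg = BalancerConfig(G=config.G, N=config.N, seed=seeds["balance"],
                              init_fraction=config.init_fraction,
                              escape_threshold=config.escape_threshold)
        result = balance(X_train, bcfg)
        sel = result.accepted_indices
        logger.info("balancing: kept %d of %d training samples", len(sel), len(idx_train))
        X_fit, y_fit = X_train[sel], y_train[sel]
    else:
        X_fit, y_fit = X_train, y_train

    spec = dataclasses.replace(config.classifier, seed=seeds["train"])
    model = train(X_fit, y_fit, spec, feature_config=fc)
    y_pred = predict(model, X_test)
    report = macro_average_precision(tally(list(y_test), y_pred))
    logger.info("test MAP = %.4f over %d classes", report.map, len(report.per_class_precision))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "resolved_config.json", "w") as fh:
            json.dump({"config": config.to_dict(), "stage_seeds": seeds},
                      fh, indent=2, sort_keys=True)
        write_profiles(outdir / "profiles.tsv", ids, X, fc)
        if result is not None:
            pd.DataFrame({"id": ids[idx_train][result.accepted_indices]}).to_csv(
                outdir / "accepted_ids.tsv", sep="\t", index=False)
            summarize_diagnostics(result).to_csv(
                outdir / "diagnostics.tsv", sep="\t", index=False)
        save_model(model, outdir / "model.joblib")
        pd.DataFrame({"id": ids[idx_test], "true_label": y_test,
                      "predicted_label": y_pred}).to_csv(
            outdir / "predictions.tsv", sep="\t", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    return report


def sweep(base: RunConfig, k=None, G=None, N=None, family=None,
          balance_training=None, dataset=None) -> pd.DataFrame:
    """Cartesian sweep over any subset of {k, G, N, family, balancing}.

    One row per combination with the test MAP and wall time; failures
    are recorded in the ``error`` column and the sweep continues.
    """
    axes = {
        "k": list(k) if k is not None else [base.k],
        "G": list(G) if G is not None else [base.G],
        "N": list(N) if N is not None else [base.N],
        "family": list(family) if family is not None else [base.classifier.family],
        "balance_training": (list(balance_training) if balance_training is not None
                             else [base.balance_training]),
    }
    rows = []
    for kv in axes["k"]:
        for gv in axes["G"]:
            for nv in axes["N"]:
                for fam in axes["family"]:
                    for bal in axes["balance_training"]:
                        cfg = dataclasses.replace(
                            base, k=kv, G=gv, N=nv, balance_training=bal,
                            classifier=dataclasses.replace(base.classifier, family=fam))
                        row = {"k": kv, "G": gv, "N": nv, "family": fam,
                               "balanced": bal, "map": np.nan,
                               "runtime_s": np.nan, "error": ""}
                        t0 = time.perf_counter()
                        try:
                            row["map"] = run_pipeline(cfg, dataset=dataset).map
                        except Exception as exc:  # keep sweeping
                            row["error"] = f"{type(exc).__name__}: {exc}"
                        row["runtime_s"] = time.perf_counter() - t0
                        rows.append(row)
    return pd.DataFrame(rows)


def cross_validate(X, labels, spec: ClassifierSpec, n_folds: int = 5, seed: int = 0,
                   balancer: BalancerConfig | None = None) -> list[float]:
    """Stratified k-fold MAP; folds partition the samples disjointly.

    When ``balancer`` is given, each training fold is balanced before
    fitting (validation folds never are).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = []
    for fold, (tr, va) in enumerate(skf.split(X, labels)):
        X_fit, y_fit = X[tr], labels[tr]
        if balancer is not None:
            res = balance(X_fit, dataclasses.replace(balancer, seed=balancer.seed + fold))
            X_fit, y_fit = X_fit[res.accepted_indices], y_fit[res.accepted_indices]
        model = train(X_fit, list(y_fit), dataclasses.replace(spec, seed=spec.seed + fold))
        pred = predict(model, X[va])
        scores.append(macro_average_precision(tally(list(labels[va]), pred)).map)
    return scores


# ---------------------------------------------------------------------------
# Reference experiments (shared by the test suite and the acceptance script)
# ---------------------------------------------------------------------------

def balanced_vs_random_experiment(seed: int, n_train: int = 2000, n_test: int = 800,
                                  k: int = 3, G: int = 10, N: int = 800,
                                  family: str = "bagged_trees") -> dict:
    """Feature-space balancing versus size-matched random undersampling.

    Trains the same classifier on (a) the balanced subset of a densely
    imbalanced training set (``blob_imbalanced``) and (b) a random
    subset of identical size, then evaluates both on a class-balanced
    test set. Also reports the Spearman correlation between a cell's
    pre-balancing occupancy and the number of samples removed from it.
    """
    seeds = fan_out_seeds(seed)
    fc = FeatureConfig(k=k)
    train_ds = generate(preset_benchmark("blob_imbalanced", n_train, seed=seeds["synthesis"]))
    test_ds = generate(preset_benchmark("separated4", n_test, seed=seeds["split"]))

    X_train, kept = profile_matrix(train_ds.records, fc)
    y_train = np.array([train_ds.labels[i] for i in kept])
    X_test, kept_t = profile_matrix(test_ds.records, fc)
    y_test = [test_ds.labels[i] for i in kept_t]

    result = balance(X_train, BalancerConfig(G=G, N=N, seed=seeds["balance"]))
    bal_idx = result.accepted_indices
    rng = np.random.default_rng(seeds["subset"])
    rand_idx = rng.choice(len(y_train), size=len(bal_idx), replace=False)

    maps = {}
    for name, sel in (("balanced", bal_idx), ("random", rand_idx)):
        model = train(X_train[sel], list(y_train[sel]),
                      ClassifierSpec(family, seed=seeds["train"]), feature_config=fc)
        maps[name] = macro_average_precision(tally(y_test, predict(model, X_test))).map

    diag = summarize_diagnostics(result)
    rho = spearmanr(diag["c_before"], -diag["delta_c"]).statistic
    return {"map_balanced": maps["balanced"], "map_random": maps["random"],
            "n_kept": int(len(bal_idx)), "spearman_density_removal": float(rho)}


def separated4_experiment(seed: int, k: int = 3, n_train: int = 2000, n_test: int = 800,
                          family: str = "subspace_knn") -> float:
    """Test MAP of one classifier on the well-separated 4-class preset."""
    seeds = fan_out_seeds(seed)
    fc = FeatureConfig(k=k)
    ds = generate(preset_benchmark("separated4", n_train + n_test, seed=seeds["synthesis"]))
    X, kept = profile_matrix(ds.records, fc)
    y = np.array([ds.labels[i] for i in kept])
    idx_train, idx_test = train_test_split(
        np.arange(len(y)), test_size=n_test, stratify=y, random_state=seeds["split"])
    model = train(X[idx_train], list(y[idx_train]),
                  ClassifierSpec(family, seed=seeds["train"]), feature_config=fc)
    pred = predict(model, X[idx_test])
    return macro_average_precision(tally(list(y[idx_test]), pred)).map


def k_sweep_experiment(seed: int, ks=(1, 3), family: str = "subspace_knn") -> dict[int, float]:
    """MAP as a function of word length k on the separated preset."""
    return {kv: separated4_experiment(seed, k=kv, family=family) for kv in ks}
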