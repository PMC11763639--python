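"""The simulated-EEG comparison study: seven algorithms, five metrics.

Generates a batch of simulated recordings (fresh mixing matrix and trial
stream per dataset), clusters each with the main pipeline and the six
baselines, and scores every clustering with ARI/NMI/Purity/F1 against the
known state sequence plus the Riemannian silhouette.

Scoring granularity follows each algorithm's native output: the sample-level
algorithms (GFP, GMM) are scored per sample over the whole record, the
window-level algorithms on their window labels against the window-center
truth. The silhouette is computed for every algorithm on one common
footing — the Riemannian distance matrix of the main pipeline's windows —
by reading each labeling at those window centers.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import baselines as bl
from .dec import EncoderSpec
from .metrics import METRIC_NAMES, compare_algorithms, score_labels
from .pipeline import RunConfig, labels_to_sequence, run_spade, segment_truth
from .segment import EEGRecord, covariance_set, segment
from .simulate import SimulationConfig, make_dataset

__all__ = ["ALGORITHMS", "run_single_dataset", "run_simulation_study",
           "study_means", "compare_study"]

logger = logging.getLogger(__name__)

ALGORITHMS = ("gfp", "gmm", "softdtw", "scm_kmeans", "ae_kmeans",
              "tangent_kmeans", "spade")

_SAMPLE_LEVEL = {"gfp", "gmm"}


def run_single_dataset(sim_config: SimulationConfig, run_config: RunConfig,
                       algorithms: tuple[str, ...] = ALGORITHMS,
                       softdtw_window_ms: float = 100.0) -> pd.DataFrame:
    """Cluster one simulated recording with the requested algorithms and score it.

    Returns a tidy frame (algorithm, metric, value). The soft-DTW baseline
    uses its own (shorter) window; all other window-level algorithms share
    the main pipeline's windows and SCMs.
    """
    ds = make_dataset(sim_config)
    record = EEGRecord(ds.data, sim_config.srate_hz)
    seed = run_config.seed

    spade_res = run_spade(record, run_config)
    segs = spade_res.segments
    covs = spade_res.covariances
    D_src = spade_res.D_source
    seg_truth = segment_truth(ds.truth, segs)
    centers = segs.centers

    rows = []

    def add(name: str, metrics: dict[str, float]) -> None:
        for metric, value in metrics.items():
            rows.append({"algorithm": name, "metric": metric, "value": value})

    for name in algorithms:
        if name == "spade":
            add(name, score_labels(spade_res.segment_labels, seg_truth, D_src))
        elif name == "gfp":
            labels = bl.gfp_microstates(record, run_config.n_clusters, seed=seed)
            add(name, score_labels(labels, ds.truth, D_src,
                                   silhouette_labels=labels[centers]))
        elif name == "gmm":
            labels = bl.gmm_cluster(record, run_config.n_clusters, seed=seed)
            add(name, score_labels(labels, ds.truth, D_src,
                                   silhouette_labels=labels[centers]))
        elif name == "softdtw":
            t100 = record.ms_to_samples(softdtw_window_ms)
            segs100 = segment(record, t100, run_config.step_samples)
            labels = bl.softdtw_cluster(segs100, run_config.n_clusters, seed=seed)
            seq = labels_to_sequence(labels, segs100.starts, t100,
                                     record.n_samples, record.srate_hz)
            add(name, score_labels(labels, segment_truth(ds.truth, segs100), D_src,
                                   silhouette_labels=seq.labels[centers]))
        elif name == "scm_kmeans":
            labels = bl.scm_vector_kmeans(covs, run_config.n_clusters, seed=seed)
            add(name, score_labels(labels, seg_truth, D_src))
        elif name == "ae_kmeans":
            labels = bl.ae_kmeans(covs, run_config.encoder,
                                  run_config.n_clusters, seed=seed)
            add(name, score_labels(labels, seg_truth, D_src))
        elif name == "tangent_kmeans":
            labels = bl.tangent_kmeans(covs, run_config.n_clusters, seed=seed)
            add(name, score_labels(labels, seg_truth, D_src))
        else:
            raise ValueError(f"unknown algorithm {name!r}")
    return pd.DataFrame(rows)


def run_simulation_study(n_datasets: int = 30, seed: int = 0,
                         algorithms: tuple[str, ...] = ALGORITHMS,
                         sim_config: SimulationConfig | None = None,
                         run_config: RunConfig | None = None) -> pd.DataFrame:
    """The full comparison study over ``n_datasets`` simulated recordings.

    Each dataset gets its own mixing matrix and trial stream (seeds spawned
    from ``seed``); clustering seeds vary per dataset too. Returns a tidy
    frame (dataset, algorithm, metric, value).
    """
    base = sim_config or SimulationConfig()
    run_base = run_config or RunConfig()
    rng = np.random.default_rng(seed)
    frames = []
    for d in range(n_datasets):
        mix_seed, trial_seed, clust_seed = rng.integers(0, 2 ** 31, size=3)
        cfg = base.replace(mixing_seed=int(mix_seed), trial_seed=int(trial_seed))
        rc = dataclasses.replace(run_base, seed=int(clust_seed))
        frame = run_single_dataset(cfg, rc, algorithms)
        frame.insert(0, "dataset", d)
        frames.append(frame)
        logger.info("dataset %d/%d done", d + 1, n_datasets)
    return pd.concat(frames, ignore_index=True)


def study_means(results: pd.DataFrame) -> pd.DataFrame:
    """Mean score per algorithm × metric (wide table, metrics as columns)."""
    wide = results.pivot_table(index="algorithm", columns="metric",
                               values="value", aggfunc="mean")
    cols = [m for m in METRIC_NAMES if m in wide.columns]
    return wide[cols]


def compare_study(results: pd.DataFrame, reference: str = "spade",
                  alpha: float = 0.05):
    """Paired tests of every baseline against the reference, per metric."""
    out = {}
    for metric in results["metric"].unique():
        sub = results[results["metric"] == metric]
        wide = sub.pivot(index="dataset", columns="algorithm", values="value")
        scores = {alg: wide[alg].to_numpy() for alg in wide.columns}
        out[metric] = compare_algorithms(scores, reference=reference,
                                         alpha=alpha, metric=metric)
    return out
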