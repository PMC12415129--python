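"""Model/Results front-end for the whole grading workflow.

:class:`GranulosaFertilityModel` is built from two annotated count
matrices (a monotocous-like and a polytocous-like sample) plus the stage
parameters; :meth:`~GranulosaFertilityModel.fit` runs the full procedure —
QC, per-million normalization, cross-sample differential expression,
Leiden purity pseudo-labeling, classifier training, and
confidence-thresholded FS quantification — and returns a
:class:`GranulosaFertilityResults` carrying every intermediate table, the
fitted classifier bundle, the per-sample FS percentages and the DEG-overlap
validation, with a ``summary()`` in the spirit of a regression results
printout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import anndata as ad
from anndata import AnnData

from . import clustering, dge, qc, quantify
from .errors import LabelingError, ParameterError
from .net import (
    MetricsReport,
    ModelBundle,
    ModelConfig,
    evaluate,
    saliency,
    train,
)
from .simulate import (
    MONO,
    POLY,
    NORM_STATE_KEY,
    GroundTruth,
    SimulationConfig,
    generate_two_sample_dataset,
)


def feature_order(deg_table: pd.DataFrame) -> list[str]:
    """Model input gene order: descending |log2FC|, then ascending q, id.

    The recurrent layer's output depends on feature order, so the order is
    fixed here and persisted in the fitted bundle.
    """
    sig = deg_table[deg_table["significant"]].copy()
    sig["_abs"] = sig["log2fc"].abs()
    sig = sig.sort_values(["_abs", "qval", "gene"], ascending=[False, True, True])
    return sig["gene"].tolist()


@dataclass
class GranulosaFertilityResults:
    """Estimates and diagnostics from a fitted grading model."""

    model: "GranulosaFertilityModel"
    qc_logs: dict[str, dict]
    deg_table: pd.DataFrame
    gene_order: list[str]
    assignment: np.ndarray
    composition: pd.DataFrame
    cluster_labels: pd.DataFrame
    training_log: dict
    bundle: ModelBundle
    metrics: MetricsReport
    classification: quantify.ClassificationResult
    within_sample_deg: dict[str, pd.DataFrame]
    overlap: quantify.OverlapResult
    truth_diagnostics: dict = field(default_factory=dict)

    # ------------------------------------------------------------------ #
    @property
    def fs_percentages(self) -> pd.Series:
        """Headline estimate: FS share of confident cells per sample (%)."""
        s = self.classification.summary.set_index("sample")["fs_pct_confident"]
        s.name = "fs_pct_confident"
        return s

    @property
    def n_model_training_degs(self) -> int:
        return len(self.gene_order)

    def saliency(self, sample: str | None = None) -> pd.DataFrame:
        """Per-gene saliency over the cells of one sample (or all)."""
        X = self.model._scaled_profiles(self.bundle, sample)
        return saliency(self.bundle, X)

    # ------------------------------------------------------------------ #
    def summary(self) -> str:
        m = self.metrics
        lines = [
            "Granulosa-cell fertility grading results",
            "=" * 56,
            f"Model-training DEGs (features): {self.n_model_training_degs}",
            f"Leiden clusters: {self.composition.shape[0]}  "
            f"(FS clusters: {sorted(self.cluster_labels.loc[self.cluster_labels.label == 'FS', 'cluster'])}, "
            f"NFS clusters: {sorted(self.cluster_labels.loc[self.cluster_labels.label == 'NFS', 'cluster'])})",
            f"Pseudo-labeled training cells: {self.training_log['n_fs']} FS / "
            f"{self.training_log['n_nfs']} NFS",
            "-" * 56,
            "Held-out test metrics (FS = positive class):",
            f"  accuracy  {m.accuracy:6.2f}%    precision {m.precision:6.2f}%",
            f"  recall    {m.recall:6.2f}%    F1        {m.f1:6.2f}%",
            f"  confusion TP={m.tp} FN={m.fn} TN={m.tn} FP={m.fp}",
            "-" * 56,
            f"Confidence threshold: {self.classification.threshold:.2f}",
        ]
        for _, row in self.classification.summary.iterrows():
            lines.append(
                f"  {row['sample']:<12} {int(row['n_cells']):5d} cells: "
                f"{int(row['n_fs'])} FS, {int(row['n_nfs'])} NFS, "
                f"{int(row['n_ambiguous'])} ambiguous -> "
                f"FS {row['fs_pct_confident']:.2f}% of confident "
                f"({row['fs_pct_all']:.2f}% of all)"
            )
        lines.append("-" * 56)
        lines.append(
            "DEG-set sizes: "
            + ", ".join(f"{k}={v}" for k, v in self.overlap.set_sizes.items())
        )
        lines.append(
            f"Common to all three sets: {self.overlap.regions['abc']} genes "
            f"(universe {self.overlap.universe})"
        )
        for _, row in self.overlap.pairwise.iterrows():
            lines.append(
                f"  overlap {row['pair']}: {int(row['overlap'])} genes, "
                f"hypergeometric p = {row['pvalue']:.3g}"
            )
        if self.truth_diagnostics:
            t = self.truth_diagnostics
            lines.append("-" * 56)
            lines.append(
                f"Ground truth: pseudo-label concordance "
                f"{t['pseudolabel_concordance_pct']:.2f}%, planted-DEG recovery "
                + ", ".join(
                    f"{s} {t['planted_deg_recovery_pct'][s]:.1f}%"
                    for s in t["planted_deg_recovery_pct"]
                )
            )
        return "\n".join(lines)


class GranulosaFertilityModel:
    """Fertility-grading model over a two-sample single-cell experiment.

    Parameters
    ----------
    samples
        ``{"monotocous": AnnData, "polytocous": AnnData}`` raw count
        matrices with per-cell ``sample`` and ``mito_frac`` annotations.
    qc_params, deg_thresholds, cluster_params, net_config
        Stage parameters; defaults are the published settings.
    threshold
        Confidence threshold for classifying a cell (default 0.95).
    truth
        Optional planted ground truth (synthetic data) enabling
        concordance/recovery diagnostics.
    imputer
        Optional hook applied after QC, default identity.
    """

    def __init__(
        self,
        samples: dict[str, AnnData],
        qc_params: qc.QCParams | None = None,
        deg_thresholds: dge.DEGThresholds | None = None,
        cluster_params: clustering.ClusterParams | None = None,
        net_config: ModelConfig | None = None,
        threshold: float = 0.95,
        truth: GroundTruth | None = None,
        imputer=None,
    ):
        if set(samples) != {MONO, POLY}:
            raise ParameterError(
                f"samples must be keyed by {{'{MONO}', '{POLY}'}}, got {set(samples)}"
            )
        self.samples = samples
        self.qc_params = qc_params or qc.QCParams()
        self.deg_thresholds = deg_thresholds or dge.DEGThresholds()
        self.cluster_params = cluster_params or clustering.ClusterParams()
        self.net_config = net_config or ModelConfig()
        self.threshold = threshold
        self.truth = truth
        self.imputer = imputer or qc.identity_imputer
        self._normalized: dict[str, AnnData] = {}

    # ------------------------------------------------------------------ #
    @classmethod
    def from_simulation(
        cls, sim_config: SimulationConfig | None = None, **kwargs
    ) -> "GranulosaFertilityModel":
        """Build from freshly simulated data (QC params scaled to the
        simulated depth unless given explicitly)."""
        sim_config = sim_config or SimulationConfig()
        samples, truth = generate_two_sample_dataset(sim_config)
        # synthetic signatures are short; default to the compact capacity
        if kwargs.get("net_config") is None:
            kwargs["net_config"] = ModelConfig.compact()
        if "qc_params" not in kwargs or kwargs["qc_params"] is None:
            kwargs["qc_params"] = qc.QCParams(
                min_total_counts=max(1, int(0.1 * sim_config.base_mean * sim_config.n_genes)),
                min_genes=max(1, sim_config.n_genes // 10),
                max_mito_fraction=0.25,
            )
        return cls(samples, truth=truth, **kwargs)

    @classmethod
    def from_mtx(cls, mono_path, poly_path, **kwargs) -> "GranulosaFertilityModel":
        from .io import read_matrix

        mono = read_matrix(mono_path)
        poly = read_matrix(poly_path)
        mono.obs["sample"] = pd.Categorical([MONO] * mono.n_obs, categories=[MONO, POLY])
        poly.obs["sample"] = pd.Categorical([POLY] * poly.n_obs, categories=[MONO, POLY])
        return cls({MONO: mono, POLY: poly}, **kwargs)

    # ------------------------------------------------------------------ #
    def _scaled_profiles(self, bundle: ModelBundle, sample: str | None = None):
        """Scaled DEG profiles for one sample (or pooled), via the
        persisted scaler."""
        mats = (
            [self._normalized[sample]]
            if sample is not None
            else [self._normalized[MONO], self._normalized[POLY]]
        )
        Xs = []
        for m in mats:
            scaled, _ = qc.log_and_scale(m, bundle.gene_order, bundle.scaler)
            Xs.append(np.asarray(scaled.X))
        return np.vstack(Xs)

    # ------------------------------------------------------------------ #
    def fit(self) -> GranulosaFertilityResults:
        # --- stage 1: QC and normalization
        qc_logs: dict[str, dict] = {}
        for name, adata in self.samples.items():
            filtered = qc.filter_cells(adata, self.qc_params)
            filtered = self.imputer(filtered)
            qc_logs[name] = dict(filtered.uns["qc_log"])
            self._normalized[name] = qc.per_million_normalize(filtered)
        norm_mono, norm_poly = self._normalized[MONO], self._normalized[POLY]

        # --- stage 2: cross-sample DGE (A = polytocous) and features
        deg_table = dge.rank_genes(norm_poly, norm_mono, self.deg_thresholds)
        gene_order = feature_order(deg_table)
        if not gene_order:
            raise LabelingError(
                "no model-training DEGs passed the thresholds; lower the "
                "fold-change/FDR thresholds or check the input data"
            )

        # --- stage 3: clustering on pooled scaled DEG profiles
        pooled = ad.concat(
            [norm_mono, norm_poly], join="inner", merge="same", uns_merge=None
        )
        pooled.uns[NORM_STATE_KEY] = "per_million"
        pooled_scaled, _ = qc.log_and_scale(pooled, gene_order)  # joint fit
        assignment = clustering.leiden_cluster(pooled_scaled, self.cluster_params)
        composition = clustering.cluster_composition(
            assignment, pooled_scaled.obs["sample"].to_numpy()
        )
        labels = clustering.select_fs_nfs(composition, self.cluster_params)
        training = clustering.build_training_set(pooled_scaled, assignment, labels)
        training_log = dict(training.uns["training_set_log"])

        # --- stage 4: classifier training on pseudo-labeled cells
        # refit the scaler on the training cells only and persist it
        training_pm = pooled[training.obs_names].copy()
        training_pm.uns[NORM_STATE_KEY] = "per_million"
        train_scaled, scaler = qc.log_and_scale(training_pm, gene_order)
        y = (training.obs["pseudo_label"] == "FS").to_numpy().astype(int)
        bundle, X_test, y_test = train(
            np.asarray(train_scaled.X),
            y,
            config=self.net_config,
            gene_order=gene_order,
            scaler=scaler,
            cell_ids=list(training.obs_names),
        )
        metrics = evaluate(bundle, X_test, y_test)

        # --- stage 5: thresholded classification of every retained cell
        X_all = self._scaled_profiles(bundle)
        cell_ids = list(norm_mono.obs_names) + list(norm_poly.obs_names)
        sample_tags = [MONO] * norm_mono.n_obs + [POLY] * norm_poly.n_obs
        probs = bundle.predict_proba(X_all)
        classification = quantify.classify_with_threshold(
            probs, self.threshold, cell_ids=cell_ids, sample=sample_tags
        )

        # --- stage 6: within-sample DGE between predicted classes
        within: dict[str, pd.DataFrame] = {}
        for name in (POLY, MONO):
            mask = classification.sample == name
            sub = quantify.ClassificationResult(
                probabilities=classification.probabilities[mask],
                labels=classification.labels[mask],
                threshold=self.threshold,
            )
            within[name] = quantify.within_sample_dge(
                self._normalized[name], sub, self.deg_thresholds
            )

        # --- stage 7: overlap validation
        tested_sets = [
            set(t.loc[t["tested"], "gene"])
            for t in (deg_table, within[POLY], within[MONO])
        ]
        universe = len(set.intersection(*tested_sets))
        overlap = quantify.overlap_report(
            gene_order,
            dge.significant_genes(within[POLY]),
            dge.significant_genes(within[MONO]),
            universe,
        )

        truth_diag = (
            self._truth_diagnostics(training, classification, within)
            if self.truth is not None
            else {}
        )
        return GranulosaFertilityResults(
            model=self,
            qc_logs=qc_logs,
            deg_table=deg_table,
            gene_order=gene_order,
            assignment=assignment,
            composition=composition,
            cluster_labels=labels,
            training_log=training_log,
            bundle=bundle,
            metrics=metrics,
            classification=classification,
            within_sample_deg=within,
            overlap=overlap,
            truth_diagnostics=truth_diag,
        )

    # ------------------------------------------------------------------ #
    def _truth_diagnostics(self, training, classification, within) -> dict:
        truth = self.truth
        planted = pd.concat([truth.cell_state[MONO], truth.cell_state[POLY]])
        train_states = planted.reindex(training.obs_names)
        concord = float(
            (train_states.to_numpy() == training.obs["pseudo_label"].to_numpy()).mean()
        )
        planted_set = set(truth.deg_genes)
        recovery = {}
        background_fp = {}
        for name, table in within.items():
            found = set(dge.significant_genes(table))
            recovery[name] = 100.0 * len(found & planted_set) / len(planted_set)
            background_fp[name] = len(found - planted_set)
        # planted FS share among confidently classified cells, per sample
        fs_true_pct = {}
        for name in (MONO, POLY):
            mask = (classification.sample == name) & (
                classification.labels != quantify.AMBIGUOUS
            )
            cells = classification.labels.index[mask]
            states = planted.reindex(cells)
            fs_true_pct[name] = (
                100.0 * float((states == "FS").mean()) if len(cells) else np.nan
            )
        return {
            "pseudolabel_concordance_pct": 100.0 * concord,
            "planted_deg_recovery_pct": recovery,
            "background_false_positives": background_fp,
            "planted_fs_pct_confident": fs_true_pct,
        }
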