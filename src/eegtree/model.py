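"""The end-to-end analysis as a model/results pair.

:class:`PLINetworkModel` is built from a subject table plus one recording
per subject and condition; :meth:`PLINetworkModel.fit` runs the full chain

    condition -> channel exclusion -> epoch selection -> average reference
    -> band decomposition -> Hilbert phase -> PLI matrices -> MST
    -> metric panel -> (ART/parametric) ANOVA, post-hocs, correlations

and returns a :class:`PLINetworkResults` holding the per-subject metric
panel and the statistical report, with ``summary()`` and simple plotting.
"""

from __future__ import annotations

import json
import platform
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .config import PipelineConfig
from .connectivity import instantaneous_phase, pli_matrix, roi_mean_pli
from .containers import Recording
from .msttree import METRIC_NAMES, aggregate_subject, build_mst, tree_metrics
from .preprocess import (
    band_decompose,
    condition_signal,
    drop_channels,
    epoch_and_select,
    rereference_average,
)
from .stats import (
    StatReport,
    art_anova,
    bonferroni,
    mixed_anova,
    perm_correlation,
    posthoc_bonferroni,
    transform_and_gate,
)
from .synthetic import CohortSpec, generate_cohort

__all__ = ["PLINetworkModel", "PLINetworkResults", "run_pipeline", "stat_stage"]


class PLINetworkModel:
    """Resting-state PLI/MST network analysis over a subject cohort.

    Parameters
    ----------
    subjects
        DataFrame with at least ``subject_id`` and ``group``; ``age``,
        ``iq`` (covariates) and ``acc`` (behavior) enable the
        corresponding parts of the statistical stage.
    recordings
        Mapping ``(subject_id, condition) -> Recording``; every subject
        needs one recording per condition.
    config
        :class:`PipelineConfig`; defaults follow the standard protocol.
    """

    def __init__(
        self,
        subjects: pd.DataFrame,
        recordings: Mapping[tuple[str, str], Recording],
        config: PipelineConfig | None = None,
        conditions: tuple[str, ...] = ("EC", "EO"),
    ) -> None:
        self.subjects = pd.DataFrame(subjects).reset_index(drop=True)
        self.recordings = dict(recordings)
        self.config = config or PipelineConfig()
        self.conditions = conditions
        if "subject_id" not in self.subjects or "group" not in self.subjects:
            raise ValueError("subject table needs subject_id and group columns")
        for sid in self.subjects["subject_id"]:
            for cond in conditions:
                if (sid, cond) not in self.recordings:
                    raise ValueError(
                        f"missing {cond} recording for subject {sid}"
                    )

    @classmethod
    def from_cohort(
        cls, spec: CohortSpec, config: PipelineConfig | None = None
    ) -> "PLINetworkModel":
        """Build the model from a synthetic cohort specification."""
        subjects, recordings = generate_cohort(spec)
        return cls(subjects, recordings, config, conditions=spec.conditions)

    # -- stage 1: recordings -> per-subject metric panel ----------------
    def _process_recording(
        self, rec: Recording, bands: Sequence[str] | None = None
    ) -> dict[str, dict[str, float]]:
        cfg = self.config
        rec = condition_signal(rec, cfg.filter_low, cfg.filter_high,
                               cfg.resample_rate, order=cfg.filter_order)
        eye = [c for c in cfg.eye_channels if c in rec.labels]
        if eye:
            rec = drop_channels(rec, eye)
        ep = epoch_and_select(rec, cfg.epoch_length, cfg.n_epochs,
                              cfg.reject_threshold)
        ep = rereference_average(ep)
        use_bands = (cfg.bands if bands is None
                     else tuple(b for b in cfg.bands if b.name in bands))
        per_band = band_decompose(ep, use_bands, order=cfg.filter_order)

        label_set = set(rec.labels)
        roi_pairs = []
        names = sorted(cfg.rois)
        for k, a in enumerate(names):
            for b in names[k + 1:]:
                if set(cfg.rois[a]) <= label_set and set(cfg.rois[b]) <= label_set:
                    roi_pairs.append((a, b))

        out: dict[str, dict[str, float]] = {}
        for band, bep in per_band.items():
            ph = instantaneous_phase(bep, cfg.edge_fraction)
            stack = pli_matrix(ph)
            epoch_metrics = []
            roi_vals = {pair: [] for pair in roi_pairs}
            for e in range(stack.n_epochs):
                m = stack.epoch(e)
                tree = build_mst(m, eps=cfg.eps)
                epoch_metrics.append(tree_metrics(tree))
                for a, b in roi_pairs:
                    roi_vals[(a, b)].append(
                        roi_mean_pli(m, a, b, cfg.rois, stack.labels)
                    )
            agg = aggregate_subject(epoch_metrics).as_dict()
            for (a, b), vals in roi_vals.items():
                agg[f"pli_{a}_{b}"] = float(np.mean(vals))
            out[band] = agg
        return out

    def compute_metrics(self, bands: Sequence[str] | None = None) -> pd.DataFrame:
        """Run preprocessing/connectivity/MST for every recording.

        Returns one row per subject x condition x band with the metric
        panel (and ROI-pair PLI where the montage carries the ROI
        electrodes).  ``bands`` restricts the analysis to a subset.
        """
        rows = []
        for _, srow in self.subjects.iterrows():
            sid = srow["subject_id"]
            for cond in self.conditions:
                rec = self.recordings[(sid, cond)]
                try:
                    per_band = self._process_recording(rec, bands)
                except Exception as exc:
                    raise RuntimeError(
                        f"pipeline failed for subject {sid}, condition "
                        f"{cond}: {exc}"
                    ) from exc
                for band, vals in per_band.items():
                    if bands is not None and band not in bands:
                        continue
                    rows.append({"subject_id": sid, "condition": cond,
                                 "band": band, **vals})
        metrics = pd.DataFrame(rows)
        return metrics.merge(self.subjects, on="subject_id", how="left")

    # -- stage 2: metric panel -> statistics ----------------------------
    def _stat_stage(
        self,
        metrics: pd.DataFrame,
        analyze: Sequence[str],
        behavior: str | None,
    ) -> StatReport:
        return stat_stage(metrics, analyze, self.config,
                          self.conditions, behavior)

    def fit(
        self,
        metrics: Sequence[str] | None = None,
        bands: Sequence[str] | None = None,
        behavior: str | None = "acc",
    ) -> "PLINetworkResults":
        """Run the full pipeline and return the results object.

        ``metrics`` restricts the statistical stage to a subset of the
        panel (default: the whole panel plus any ROI-pair PLI columns);
        ``behavior=None`` skips the correlation stage.
        """
        panel = self.compute_metrics(bands=bands)
        if behavior is not None and behavior not in panel.columns:
            behavior = None
        if metrics is None:
            roi_cols = [c for c in panel.columns if c.startswith("pli_")]
            analyze = list(METRIC_NAMES) + roi_cols
            # the compatibility diameter is linearly dependent on leaf
            analyze.remove("reported_diameter")
        else:
            analyze = list(metrics)
        report = self._stat_stage(panel, analyze, behavior)
        return PLINetworkResults(self, panel, report, tuple(analyze))


@dataclass
class PLINetworkResults:
    """Fitted pipeline: metric panel + statistical report."""

    model: PLINetworkModel
    metrics: pd.DataFrame
    report: StatReport
    analyzed: tuple[str, ...] = ()

    @property
    def anova(self) -> pd.DataFrame:
        return self.report.anova

    @property
    def posthoc(self) -> pd.DataFrame:
        return self.report.posthoc

    @property
    def correlations(self) -> pd.DataFrame:
        return self.report.correlations

    def significant_interactions(self) -> pd.DataFrame:
        return self.report.significant("interaction")

    def summary(self) -> str:
        """Readable run summary: design, routes, significant effects."""
        lines = []
        subj = self.model.subjects
        sizes = subj.groupby("group", observed=True).size()
        lines.append("PLI / MST network analysis")
        lines.append("=" * 60)
        lines.append(
            "groups: " + ", ".join(f"{g} (n={n})" for g, n in sizes.items())
        )
        bands = sorted(self.metrics["band"].unique())
        lines.append(f"bands: {', '.join(bands)}; "
                     f"conditions: {', '.join(self.model.conditions)}")
        lines.append(f"alpha = {self.report.alpha}, "
                     f"permutations = {self.report.n_perm}")
        if len(self.report.routes):
            n_art = int((self.report.routes["route"] == "ART").sum())
            lines.append(
                f"routes: {n_art} metric/band cells via ART, "
                f"{int((self.report.routes['route'] == 'parametric').sum())} "
                "parametric"
            )
        sig = self.significant_interactions()
        lines.append("")
        lines.append("group x condition interactions (p < alpha):")
        if len(sig):
            for _, r in sig.iterrows():
                lines.append(
                    f"  {r['metric']:<18s} {r['band']:<6s} "
                    f"F({int(r['DF1'])}, {int(r['DF2'])}) = {r['F']:.3f}, "
                    f"p = {r['p']:.4f}, eta2 = {r['eta_sq']:.3f} [{r['route']}]"
                )
        else:
            lines.append("  none")
        if len(self.correlations):
            lines.append("")
            lines.append("behavior correlations (permutation test):")
            sig_c = self.correlations[
                self.correlations["p_corr"] < self.report.alpha
            ]
            for _, r in sig_c.iterrows():
                lines.append(
                    f"  {r['metric']:<18s} {r['band']:<6s} "
                    f"r = {r['r']:+.3f}, p_perm = {r['p_perm']:.4f}, "
                    f"p_corr = {r['p_corr']:.4f} (n = {int(r['n'])})"
                )
            if not len(sig_c):
                lines.append("  none significant after correction")
        return "\n".join(lines)

    def plot_metric(self, metric: str, band: str, ax=None):
        """Group x condition boxplot of one metric in one band."""
        import matplotlib.pyplot as plt

        df = self.metrics[self.metrics["band"] == band]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        groups = sorted(df["group"].unique())
        conds = list(self.model.conditions)
        data, positions, colors = [], [], []
        cmap = plt.get_cmap("tab10")
        for ci, cond in enumerate(conds):
            for gi, g in enumerate(groups):
                sel = df[(df["group"] == g) & (df["condition"] == cond)]
                data.append(sel[metric].to_numpy())
                positions.append(ci * (len(groups) + 1) + gi)
                colors.append(cmap(gi))
        bp = ax.boxplot(data, positions=positions, patch_artist=True,
                        widths=0.7)
        for patch, c in zip(bp["boxes"], colors):
            patch.set_facecolor(c)
        ax.set_xticks([ci * (len(groups) + 1) + (len(groups) - 1) / 2
                       for ci in range(len(conds))])
        ax.set_xticklabels(conds)
        ax.set_ylabel(metric)
        ax.set_title(f"{metric} ({band})")
        handles = [plt.Line2D([], [], color=cmap(gi), lw=6, label=g)
                   for gi, g in enumerate(groups)]
        ax.legend(handles=handles, frameon=False)
        return ax

    def save(self, output_dir: str | Path) -> Path:
        """Write metrics, report tables and a reproducibility manifest."""
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        self.report.routes.to_csv(out / "routes.csv", index=False)
        self.report.anova.to_csv(out / "anova.csv", index=False)
        self.report.posthoc.to_csv(out / "posthoc.csv", index=False)
        self.report.correlations.to_csv(out / "correlations.csv", index=False)
        (out / "report.json").write_text(json.dumps({
            "anova": self.report.anova.to_dict(orient="records"),
            "posthoc": self.report.posthoc.to_dict(orient="records"),
            "correlations": self.report.correlations.to_dict(orient="records"),
        }, indent=1, default=str))
        manifest = {
            "config_digest": self.model.config.digest(),
            "config": self.model.config.to_dict(),
            "seed": self.model.config.seed,
            "n_subjects": int(len(self.model.subjects)),
            "eegtree_version": _version,
            "python": platform.python_version(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return out


def run_pipeline(
    config: PipelineConfig,
    subjects: pd.DataFrame,
    recordings: Mapping[tuple[str, str], Recording],
    output_dir: str | Path,
    bands: Sequence[str] | None = None,
) -> PLINetworkResults:
    """Convenience wrapper: build the model, fit, and write all outputs."""
    model = PLINetworkModel(subjects, recordings, config)
    results = model.fit(bands=bands)
    results.save(output_dir)
    return results


def stat_stage(
    metrics: pd.DataFrame,
    analyze: Sequence[str],
    config: PipelineConfig,
    conditions: tuple[str, ...] = ("EC", "EO"),
    behavior: str | None = "acc",
) -> StatReport:
    """Statistical stage over a computed metric panel.

    For each metric x band: log transform, Shapiro-Wilk normality gate,
    parametric or ART mixed ANOVA (group x condition, age/IQ residualized
    out when present), Bonferroni post-hocs when the interaction is
    significant, and permutation-tested Pearson correlations between the
    first condition's metric values and the behavioral score.
    """
    cfg = config
    has_cov = {"age", "iq"} <= set(metrics.columns)
    covariates = ("age", "iq") if has_cov else ()
    route_rows, anova_rows, post_rows, corr_rows = [], [], [], []
    for band, bdf in metrics.groupby("band", observed=True):
        for metric in analyze:
            if metric not in bdf.columns:
                continue
            vals = bdf[metric]
            if vals.isna().any() or (vals <= 0).any():
                route_rows.append((metric, band, "skipped"))
                continue
            work = bdf.copy()
            work[metric] = np.log(vals.to_numpy(dtype=float))
            route, _gate = transform_and_gate(bdf, metric, ("group",),
                                              cfg.alpha)
            route_rows.append((metric, band, route))
            fn = mixed_anova if route == "parametric" else art_anova
            aov = fn(work, metric, covariates)
            aov.insert(0, "band", band)
            aov.insert(0, "metric", metric)
            anova_rows.append(aov)
            inter_p = float(
                aov.loc[aov["effect"] == "interaction", "p"].iloc[0]
            )
            if inter_p < cfg.alpha:
                ph = posthoc_bonferroni(work, metric, covariates)
                ph.insert(0, "band", band)
                ph.insert(0, "metric", metric)
                post_rows.append(ph)
        if behavior is not None and behavior in bdf.columns:
            ec = bdf[bdf["condition"] == conditions[0]]
            tested = [m for m in analyze
                      if m in ec.columns and ec[m].notna().all()
                      and np.ptp(ec[m].to_numpy(dtype=float)) > 0]
            fam = len(tested)
            for metric in tested:
                r, p = perm_correlation(
                    ec[metric].to_numpy(dtype=float),
                    ec[behavior].to_numpy(dtype=float),
                    n_perm=cfg.n_perm,
                    seed=np.random.default_rng(
                        (cfg.seed * 1000003
                         + zlib.crc32(f"{band}:{metric}".encode())) % 2**31
                    ),
                )
                corr_rows.append((metric, band, len(ec), r, p,
                                  bonferroni(p, fam)))
    routes = pd.DataFrame(route_rows, columns=["metric", "band", "route"])
    anova = (pd.concat(anova_rows, ignore_index=True)
             if anova_rows else pd.DataFrame())
    posthoc = (pd.concat(post_rows, ignore_index=True)
               if post_rows else pd.DataFrame())
    corrs = pd.DataFrame(
        corr_rows,
        columns=["metric", "band", "n", "r", "p_perm", "p_corr"],
    )
    return StatReport(routes, anova, posthoc, corrs,
                      alpha=cfg.alpha, n_perm=cfg.n_perm, seed=cfg.seed)
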