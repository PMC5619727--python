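"""Marker identification and posterior inference on selected CpGs.

Builds on the per-CpG model posteriors of :mod:`methylselect.bayes`:

* **Marker panels** — for each candidate model, CpGs are ranked by their
  posterior probability of that model and the panel is the largest
  top-ranked set whose estimated Bayes false discovery rate, the mean of
  (1 − probability) over the set, stays at or below the control level.
* **Differential methylation** — within a selected model, the posterior
  of the difference between a cell-specific partition mean and the
  pooled reference mean is normal with variance
  ``g/(1+g) · sigma2 / n · (1/c_p + 1/c_ref)``; it is summarised by a
  posterior mean, a 95% credible interval, probabilities over absolute
  difference ranges, and a hypo/hyper methylation state.
* **Sex effects** — for common markers (selected for the same model in
  both sexes), the between-sex difference of each cell-specific
  partition mean is normal with the two sexes' posterior variances
  added; a sex effect is declared when the posterior probability of an
  absolute difference of at least ``delta`` (default 0.10) exceeds the
  probability threshold (default 0.95) for some partition.
* **Validation** — training credible intervals are compared against mean
  differences recomputed in an independent dataset, restricting each
  partition to the cell types the validation data actually contains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .bayes import ModelFitPerCpG, PriorConfig
from .lineage import CandidateModel

__all__ = [
    "MarkerPanel",
    "DifferentialSummary",
    "SexEffectResult",
    "ValidationReport",
    "select_markers",
    "common_markers",
    "differential_posterior",
    "sex_effect_posterior",
    "validate_panel",
    "RANGE_BIN_EDGES",
    "RANGE_BIN_LABELS",
]

logger = logging.getLogger("methylselect")

Z_95 = 1.959964  # two-sided 95% normal quantile

#: Left-closed, right-open bins on the absolute difference.
RANGE_BIN_EDGES = (0.0, 0.10, 0.20, 0.30, 0.40, 0.50, np.inf)
RANGE_BIN_LABELS = ("<0.10", "0.10-0.20", "0.20-0.30", "0.30-0.40", "0.40-0.50", ">0.50")


@dataclass
class MarkerPanel:
    """CpGs selected for one candidate model at a Bayes FDR level."""

    model_name: str
    fdr_level: float
    probes: list[tuple[str, float]]  # (probe_id, posterior probability), desc
    realized_bayes_fdr: float

    @property
    def probe_ids(self) -> list[str]:
        return [p for p, _ in self.probes]

    def __len__(self) -> int:
        return len(self.probes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probes, columns=["probe_id", "posterior_prob"])


def select_markers(
    probe_ids,
    probs,
    fdr_level: float = 0.05,
    model_name: str = "",
) -> MarkerPanel:
    """Largest top-ranked probe set whose Bayes FDR estimate is ≤ level.

    Probes are ranked by posterior probability (descending); the Bayes FDR
    of the top-r set is the mean of (1 − probability) over it, which is
    non-decreasing in r, so the panel is the longest admissible prefix.
    Tie groups in probability are included all-in or all-out.
    """
    probs = np.asarray(probs, dtype=float)
    probe_ids = list(probe_ids)
    if len(probe_ids) != len(probs):
        raise ValueError("probe_ids and probs must have equal length")
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("posterior probabilities must lie in [0,1]")

    order = np.argsort(-probs, kind="stable")
    p_sorted = probs[order]
    if p_sorted.size == 0:
        return MarkerPanel(model_name, fdr_level, [], 0.0)

    cum_fdr = np.cumsum(1.0 - p_sorted) / np.arange(1, p_sorted.size + 1)
    # admissible cut points: end of a tie group (last index with that value)
    group_end = np.r_[p_sorted[1:] != p_sorted[:-1], True]
    ok = (cum_fdr <= fdr_level) & group_end
    if not ok.any():
        return MarkerPanel(model_name, fdr_level, [], 0.0)
    r = int(np.max(np.nonzero(ok)[0])) + 1
    chosen = order[:r]
    probes = [(str(probe_ids[i]), float(probs[i])) for i in chosen]
    return MarkerPanel(model_name, fdr_level, probes, float(cum_fdr[r - 1]))


def common_markers(panel_f: MarkerPanel, panel_m: MarkerPanel) -> set[str]:
    """Probes selected for the same candidate model in both sexes."""
    if panel_f.model_name != panel_m.model_name:
        raise ValueError(
            f"panels are for different models: {panel_f.model_name!r} vs "
            f"{panel_m.model_name!r}"
        )
    return set(panel_f.probe_ids) & set(panel_m.probe_ids)


@dataclass
class DifferentialSummary:
    """Posterior of one partition-vs-reference methylation difference."""

    probe_id: str
    model_name: str
    partition_label: str
    posterior_mean: float
    posterior_sd: float
    ci95: tuple[float, float]
    range_probs: dict[str, float]
    state: str | None  # "hypomethylated" / "hypermethylated" / None at exactly 0

    def to_row(self) -> dict:
        row = {
            "probe_id": self.probe_id,
            "model": self.model_name,
            "partition": self.partition_label,
            "mean": self.posterior_mean,
            "sd": self.posterior_sd,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
        }
        row.update(self.range_probs)
        row["state"] = self.state or "unclassified"
        return row


def _abs_range_probs(mean: float, sd: float) -> dict[str, float]:
    """P(|D| in [a,b)) for a folded-normal D ~ N(mean, sd^2)."""
    edges = np.array(RANGE_BIN_EDGES)
    if sd == 0:
        k = int(np.searchsorted(edges, abs(mean), side="right")) - 1
        out = {lab: 0.0 for lab in RANGE_BIN_LABELS}
        out[RANGE_BIN_LABELS[k]] = 1.0
        return out
    upper = norm.cdf((edges[1:] - mean) / sd) - norm.cdf((edges[:-1] - mean) / sd)
    lower = norm.cdf((-edges[:-1] - mean) / sd) - norm.cdf((-edges[1:] - mean) / sd)
    probs = upper + lower
    probs = probs / probs.sum()
    return dict(zip(RANGE_BIN_LABELS, (float(p) for p in probs)))


def differential_posterior(
    fit: ModelFitPerCpG,
    model: CandidateModel,
    prior: PriorConfig,
    n_s: int,
    baseline_index: int | None = None,
) -> list[DifferentialSummary]:
    """Normal posterior of each cell-specific partition mean minus the
    reference, for one CpG under one candidate model.

    The variance is ``g/(1+g) · sigma2_hat / n_s · (1/c_p + 1/c_ref)``.
    The saturated model has no reference; a ``baseline_index`` must be
    designated explicitly to summarise it.  The null model admits no
    differences.
    """
    ref = model.reference_index
    if ref is None:
        if model.n_partitions == 1:
            raise ValueError("null model has no differential methylation to summarise")
        if baseline_index is None:
            raise ValueError(
                "saturated model has no reference partition; designate a baseline"
            )
        ref = baseline_index
    mu = fit.mu_hat[model.name]
    sigma2 = fit.sigma2_hat[model.name]
    c = model.partition_sizes
    out = []
    for p in range(model.n_partitions):
        if p == ref:
            continue
        mean = float(mu[p] - mu[ref])
        var = prior.shrinkage * sigma2 / n_s * (1.0 / c[p] + 1.0 / c[ref])
        sd = float(np.sqrt(var))
        state = None
        if mean < 0:
            state = "hypomethylated"
        elif mean > 0:
            state = "hypermethylated"
        out.append(
            DifferentialSummary(
                probe_id=fit.probe_id,
                model_name=model.name,
                partition_label=model.group_label(p),
                posterior_mean=mean,
                posterior_sd=sd,
                ci95=(mean - Z_95 * sd, mean + Z_95 * sd),
                range_probs=_abs_range_probs(mean, sd),
                state=state,
            )
        )
    return out


@dataclass
class SexEffectResult:
    """Between-sex posterior of the cell-specific partition means of one
    CpG under one candidate model (female minus male)."""

    probe_id: str
    model_name: str
    partition_labels: list[str]
    means: np.ndarray  # per partition
    variances: np.ndarray
    prob_exceeds: np.ndarray  # P(|difference| >= delta)
    declared: bool
    delta: float
    prob_threshold: float

    def to_rows(self) -> list[dict]:
        return [
            {
                "probe_id": self.probe_id,
                "model": self.model_name,
                "partition": lab,
                "mean_diff": float(self.means[i]),
                "sd": float(np.sqrt(self.variances[i])),
                "prob_ge_delta": float(self.prob_exceeds[i]),
                "declared": bool(self.declared),
            }
            for i, lab in enumerate(self.partition_labels)
        ]


def _prob_abs_exceeds(mean: float, sd: float, delta: float) -> float:
    """P(|D| >= delta) for D ~ N(mean, sd^2)."""
    if delta <= 0:
        return 1.0
    if sd == 0:
        return float(abs(mean) >= delta)
    return float(
        norm.cdf((-delta - mean) / sd) + 1.0 - norm.cdf((delta - mean) / sd)
    )


def sex_effect_posterior(
    fit_f: ModelFitPerCpG,
    fit_m: ModelFitPerCpG,
    model: CandidateModel,
    prior_f: PriorConfig,
    prior_m: PriorConfig,
    n_f: int,
    n_m: int,
    delta: float = 0.10,
    prob_threshold: float = 0.95,
) -> SexEffectResult:
    """Posterior of female-minus-male partition means for a common marker.

    Per cell-specific partition p the difference is normal with mean
    ``mu_f,p − mu_m,p`` and variance
    ``sigma2_f · g_f/((1+g_f) n_f c_p) + sigma2_m · (same for males)``,
    the sum of the two sexes' posterior variances for that partition
    mean.  Declared when some partition's probability of an absolute
    difference ≥ delta exceeds the threshold.
    """
    if fit_f.probe_id != fit_m.probe_id:
        raise ValueError("sex-effect posterior requires the same probe in both fits")
    idx = model.cell_specific_indices
    if model.name not in fit_f.mu_hat or model.name not in fit_m.mu_hat:
        raise ValueError(f"model {model.name!r} missing from one of the fits")
    mu_f = fit_f.mu_hat[model.name]
    mu_m = fit_m.mu_hat[model.name]
    if mu_f.shape != mu_m.shape:
        raise ValueError("partition structure differs between the sexes")
    c = model.partition_sizes
    s2f = fit_f.sigma2_hat[model.name]
    s2m = fit_m.sigma2_hat[model.name]
    labels, means, variances, probs = [], [], [], []
    for p in idx:
        mean = float(mu_f[p] - mu_m[p])
        var = (
            s2f * prior_f.shrinkage / (n_f * c[p])
            + s2m * prior_m.shrinkage / (n_m * c[p])
        )
        labels.append(model.group_label(p))
        means.append(mean)
        variances.append(var)
        probs.append(_prob_abs_exceeds(mean, float(np.sqrt(var)), delta))
    probs_arr = np.array(probs)
    return SexEffectResult(
        probe_id=fit_f.probe_id,
        model_name=model.name,
        partition_labels=labels,
        means=np.array(means),
        variances=np.array(variances),
        prob_exceeds=probs_arr,
        declared=bool(probs_arr.size and (probs_arr > prob_threshold).any()),
        delta=delta,
        prob_threshold=prob_threshold,
    )


@dataclass
class ValidationReport:
    """Coverage and direction concordance of training posteriors in an
    independent dataset."""

    model_name: str
    per_probe: pd.DataFrame
    summary: dict = field(default_factory=dict)


def validate_panel(
    training: list[DifferentialSummary],
    validation_data,
    model: CandidateModel,
) -> ValidationReport:
    """Check training 95% CIs and methylation states against validation data.

    For every training summary whose probe is present in the validation
    dataset, the validation mean difference is recomputed between the
    cell types of the summarised partition and of the reference that are
    actually available (the marginal of the multivariate normal restricts
    to available coordinates).  ``covered`` means the validation
    difference lies inside the training CI; ``state_concordant`` means
    its sign matches the training state.  For multi-partition models the
    summary also reports joint coverage (all partitions of a probe
    covered).
    """
    ref = model.reference_index
    if ref is None and model.n_partitions > 1:
        raise ValueError("validation requires a model with a reference partition")
    avail = set(validation_data.cell_types)
    probe_pos = {p: i for i, p in enumerate(validation_data.probe_ids)}
    ct_pos = {ct: j for j, ct in enumerate(validation_data.cell_types)}
    vmeans = validation_data.beta.mean(axis=1)  # K × J

    group_cols: dict[str, list[int]] = {}
    for p in range(model.n_partitions):
        cols = [ct_pos[ct] for ct in model.partition[p] if ct in avail]
        group_cols[model.group_label(p)] = cols
    ref_cols = group_cols[model.group_label(ref)] if ref is not None else []
    if ref is not None and not ref_cols:
        raise ValueError("validation data contains no cell type of the reference partition")

    rows = []
    for summ in training:
        k = probe_pos.get(summ.probe_id)
        if k is None:
            continue
        cols = group_cols.get(summ.partition_label)
        if not cols:
            continue
        vdiff = float(vmeans[k, cols].mean() - vmeans[k, ref_cols].mean())
        covered = bool(summ.ci95[0] <= vdiff <= summ.ci95[1])
        if summ.state is None:
            concordant = vdiff == 0.0
        else:
            concordant = (vdiff < 0) == (summ.state == "hypomethylated")
        rows.append(
            {
                "probe_id": summ.probe_id,
                "partition": summ.partition_label,
                "training_mean": summ.posterior_mean,
                "ci_low": summ.ci95[0],
                "ci_high": summ.ci95[1],
                "validation_diff": vdiff,
                "covered": covered,
                "state_concordant": bool(concordant),
            }
        )
    per_probe = pd.DataFrame(
        rows,
        columns=[
            "probe_id", "partition", "training_mean", "ci_low", "ci_high",
            "validation_diff", "covered", "state_concordant",
        ],
    )
    report = ValidationReport(model_name=model.name, per_probe=per_probe)
    if per_probe.empty:
        logger.warning("validate_panel: no overlapping probes; empty report")
        return report

    summary: dict = {
        "coverage_pct": 100.0 * per_probe["covered"].mean(),
        "concordance_pct": 100.0 * per_probe["state_concordant"].mean(),
        "n_probes": int(per_probe["probe_id"].nunique()),
    }
    parts = per_probe["partition"].unique()
    if len(parts) > 1:
        for part in parts:
            sub = per_probe[per_probe["partition"] == part]
            summary[f"coverage_pct[{part}]"] = 100.0 * sub["covered"].mean()
            summary[f"concordance_pct[{part}]"] = 100.0 * sub["state_concordant"].mean()
        joint = per_probe.groupby("probe_id")["covered"].all()
        summary["joint_coverage_pct"] = 100.0 * joint.mean()
        joint_state = per_probe.groupby("probe_id")["state_concordant"].all()
        summary["joint_concordance_pct"] = 100.0 * joint_state.mean()
    report.summary = summary
    return report
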