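"""Synthetic cell-sorted methylation data with known ground truth.

The generator mirrors the analysis model's likelihood: for each CpG a
candidate partition model is drawn from a mixture, each partition receives
a true mean β-value (the pooled reference at a baseline level, every
cell-specific partition offset from it), and i.i.d. Gaussian noise of a
common standard deviation is added per subject and cell type.  Values are
clipped to [0,1] and clip events counted.  Optional sex effects shift one
cell-specific partition's mean between the female and male copies of a
probe.

Defaults emulate the six-population sorted-leukocyte design the method
was developed on: J = 6 cell types, 5 female and 6 male subjects, within-
CpG noise sd 0.02, cell-specific offsets around 0.3 on the β scale and
reference levels uniform on [0.2, 0.8] (keeping clipping rare), with the
twelve lineage-derived candidate models weighted equally.

A scalar ``effect_size`` e draws each partition's offset magnitude
uniformly from [0.75e, 1.25e] with a random sign, so distinct partitions
of the same probe receive distinct means almost surely; a constant
magnitude would let two same-sign partitions coincide and the realized
pattern collapse onto a coarser partition.  Saturated-model probes draw
an independent offset for every cell type.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import MethylationDataset
from .lineage import DEFAULT_CELL_TYPES, ModelSet, hematopoietic_model_set

logger = logging.getLogger("methylselect")

__all__ = ["SexShift", "SimulationConfig", "Truth", "simulate_dataset", "recovery_report"]


@dataclass
class SexShift:
    """Between-sex mean shift applied to one random cell-specific
    partition of a probe, with the given probability of occurrence."""

    prob: float = 0.05
    magnitude: float = 0.2


@dataclass
class SimulationConfig:
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    models: ModelSet | None = None
    K: int = 2000
    n_per_sex: dict = field(default_factory=lambda: {"F": 5, "M": 6})
    model_mixture: dict[str, float] | None = None
    effect_size: float | tuple[float, float] = 0.3
    baseline: float | tuple[float, float] = (0.2, 0.8)
    sigma: float = 0.02
    sex_shift: SexShift | None = field(default_factory=SexShift)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.models is None:
            if tuple(self.cell_types) != DEFAULT_CELL_TYPES:
                raise ValueError(
                    "supply an explicit ModelSet for non-default cell types"
                )
            self.models = hematopoietic_model_set()
        if self.model_mixture is not None:
            unknown = set(self.model_mixture) - set(self.models.names)
            if unknown:
                raise ValueError(f"mixture names unknown: {sorted(unknown)}")
            total = sum(self.model_mixture.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"model_mixture must sum to 1, got {total}")

    def mixture_vector(self) -> np.ndarray:
        M = len(self.models)
        if self.model_mixture is None:
            return np.full(M, 1.0 / M)
        return np.array([self.model_mixture.get(n, 0.0) for n in self.models.names])


@dataclass
class Truth:
    """Ground truth of one simulated dataset."""

    probe_ids: list[str]
    cell_types: tuple[str, ...]
    model_names: np.ndarray  # K, generating model per probe
    means: dict[str, np.ndarray]  # sex -> K × J true cell-type means
    sex_effect: np.ndarray  # K bool
    sex_effect_partition: np.ndarray  # K str ('' when no effect)
    clip_fraction: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "probe_id": self.probe_ids,
            "model": self.model_names,
            "sex_effect": self.sex_effect.astype(int),
            "sex_effect_partition": self.sex_effect_partition,
        }
        for sex, mm in sorted(self.means.items()):
            for j, ct in enumerate(self.cell_types):
                data[f"mean_{sex}:{ct}"] = mm[:, j]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Truth":
        sexes = sorted({c.split(":")[0][5:] for c in df.columns if c.startswith("mean_")})
        cts = tuple(
            c.split(":", 1)[1] for c in df.columns if c.startswith(f"mean_{sexes[0]}:")
        )
        means = {
            s: np.column_stack([df[f"mean_{s}:{ct}"].to_numpy() for ct in cts])
            for s in sexes
        }
        return cls(
            probe_ids=[str(x) for x in df["probe_id"]],
            cell_types=cts,
            model_names=df["model"].to_numpy(dtype=object),
            means=means,
            sex_effect=df["sex_effect"].to_numpy().astype(bool),
            sex_effect_partition=df["sex_effect_partition"].fillna("").to_numpy(dtype=object),
        )


def _draw_scalar_or_range(rng, value, size):
    if np.isscalar(value):
        return np.full(size, float(value))
    lo, hi = value
    return rng.uniform(lo, hi, size)


def _draw_magnitudes(rng, effect_size, size):
    if np.isscalar(effect_size):
        e = float(effect_size)
        return rng.uniform(0.75 * e, 1.25 * e, size)
    lo, hi = effect_size
    return rng.uniform(lo, hi, size)


def simulate_dataset(config: SimulationConfig) -> tuple[dict[str, MethylationDataset], Truth]:
    """Generate per-sex datasets and their ground truth.

    Deterministic given ``config.seed``.  Returns a dict keyed by the
    sexes present in ``config.n_per_sex`` and the :class:`Truth`.
    """
    rng = np.random.default_rng(config.seed)
    models = config.models
    K, J = config.K, len(config.cell_types)
    ct_col = {ct: j for j, ct in enumerate(config.cell_types)}

    model_idx = rng.choice(len(models), size=K, p=config.mixture_vector())
    baseline = _draw_scalar_or_range(rng, config.baseline, K)

    base_means = np.tile(baseline[:, None], (1, J))
    for m in range(len(models)):
        ks = np.nonzero(model_idx == m)[0]
        if ks.size == 0:
            continue
        model = models[m]
        for p in model.cell_specific_indices:
            signs = rng.choice((-1.0, 1.0), size=ks.size)
            mags = _draw_magnitudes(rng, config.effect_size, ks.size)
            cols = [ct_col[ct] for ct in model.partition[p]]
            for c in cols:
                base_means[ks, c] = baseline[ks] + signs * mags

    model_names = np.array([models[m].name for m in model_idx], dtype=object)

    # sex effects: shift one random cell-specific partition in the male copy
    sex_effect = np.zeros(K, dtype=bool)
    sex_part = np.full(K, "", dtype=object)
    sexes = sorted(config.n_per_sex)
    means = {s: base_means.copy() for s in sexes}
    if config.sex_shift is not None and len(sexes) > 1:
        for k in range(K):
            model = models[int(model_idx[k])]
            idx = model.cell_specific_indices
            if not idx or rng.random() >= config.sex_shift.prob:
                continue
            p = idx[int(rng.integers(len(idx)))]
            sign = float(rng.choice((-1.0, 1.0)))
            cols = [ct_col[ct] for ct in model.partition[p]]
            means["M"][k, cols] = base_means[k, cols] + sign * config.sex_shift.magnitude
            sex_effect[k] = True
            sex_part[k] = model.group_label(p)

    probe_ids = [f"cg{k:07d}" for k in range(K)]
    datasets: dict[str, MethylationDataset] = {}
    clip_frac: dict[str, float] = {}
    for s in sexes:
        n = int(config.n_per_sex[s])
        noise = rng.normal(0.0, config.sigma, size=(K, n, J))
        beta = means[s][:, None, :] + noise
        clipped = (beta < 0) | (beta > 1)
        frac = float(clipped.mean())
        clip_frac[s] = frac
        if frac > 0.10:
            warnings.warn(
                f"simulate_dataset: {100 * frac:.1f}% of values clipped for sex {s}; "
                "configuration is likely unrealistic",
                RuntimeWarning,
            )
        datasets[s] = MethylationDataset(
            probe_ids=list(probe_ids),
            cell_types=tuple(config.cell_types),
            subjects=[f"{s}{i + 1:02d}" for i in range(n)],
            beta=np.clip(beta, 0.0, 1.0),
            sex=s,
        )
    truth = Truth(
        probe_ids=probe_ids,
        cell_types=tuple(config.cell_types),
        model_names=model_names,
        means=means,
        sex_effect=sex_effect,
        sex_effect_partition=sex_part,
        clip_fraction=clip_frac,
    )
    return datasets, truth


def recovery_report(truth: Truth, fit, panels: dict, sex_results=None) -> dict:
    """Recovery metrics of a fit and its marker panels against the truth.

    Returns a dict with the modal-vs-generating confusion matrix and
    accuracy, per-model panel precision/recall, the pooled realized
    false-discovery proportion (0 when nothing is selected), and — when
    per-probe :class:`SexEffectResult` objects are supplied — sex-effect
    sensitivity and specificity.
    """
    probe_model = dict(zip(truth.probe_ids, truth.model_names))
    modal = fit.modal_models()
    true_per_probe = np.array([probe_model[p] for p in fit.probe_ids], dtype=object)
    confusion = pd.crosstab(
        pd.Series(true_per_probe, name="generating"),
        pd.Series(modal, name="modal"),
    )
    accuracy = float((modal == true_per_probe).mean())

    rows = []
    n_selected = n_false = 0
    for name, panel in panels.items():
        sel = set(panel.probe_ids)
        true_set = {p for p, m in probe_model.items() if m == name}
        tp = len(sel & true_set)
        fp = len(sel) - tp
        n_selected += len(sel)
        n_false += fp
        rows.append(
            {
                "model": name,
                "n_selected": len(sel),
                "n_true": len(true_set),
                "precision": tp / len(sel) if sel else 1.0,
                "recall": tp / len(true_set) if true_set else float("nan"),
                "fdp": fp / len(sel) if sel else 0.0,
            }
        )
    report = {
        "confusion": confusion,
        "modal_accuracy": accuracy,
        "per_model": pd.DataFrame(rows),
        "fdp": n_false / n_selected if n_selected else 0.0,
    }
    if sex_results is not None:
        flags = dict(zip(truth.probe_ids, truth.sex_effect))
        declared = np.array([r.declared for r in sex_results])
        is_true = np.array([flags[r.probe_id] for r in sex_results])
        report["sex_sensitivity"] = (
            float(declared[is_true].mean()) if is_true.any() else float("nan")
        )
        report["sex_specificity"] = (
            float((~declared[~is_true]).mean()) if (~is_true).any() else float("nan")
        )
    return report
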