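"""Packaged simulation experiments and small fixture generation.

Four named experiments mirror the simulation studies the package exists to
reproduce, at configurable (desk) scale:

``fig2_trace``
    Per-step c-index traces on train/validation/test under group lasso,
    lasso and no regularization.
``fig3_grid``
    Grid search over (scale, alpha) plus a replicate-level Welch
    comparison of group lasso vs lasso vs none on test data.
``fig3_groupsize``
    C-index as a function of group size with the total number of relevant
    features held fixed at 16.
``fig4_cph_compare``
    Deep model vs classical linear Cox under identity / quadratic /
    absolute feature transforms in the generative model.

Every run writes TSV tables, optional PNG plots and a JSON manifest
(config + seed + package version) into its output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluate import c_index, compare_methods, fit_cph_baseline
from .model import RegularizationConfig
from .simulate import SimulationConfig, simulate, write_dataset
from .train import TrainingConfig, grid_search, split, train

__all__ = ["ExperimentSpec", "run_experiment", "make_fixtures",
           "S1_CONFIG", "COMPARATOR_CONFIG"]

logger = logging.getLogger(__name__)

# the high-dimensional grouped simulation: 2000 groups x 4 features,
# 5 survival-relevant groups, 500 samples (features = 16 x samples)
S1_CONFIG = SimulationConfig(
    n_samples=500, n_groups=2000, group_size=4, n_relevant_groups=5, rng_seed=0
)

# low-dimensional configuration on which an unpenalized Cox fit is stable
COMPARATOR_CONFIG = SimulationConfig(
    n_samples=500, n_groups=25, group_size=4, n_relevant_groups=5, rng_seed=0
)


# per-experiment training defaults (desk scale, single CPU); the
# proximal optimizer realizes exact group sparsity, float32 halves
# memory traffic on the 8000-feature runs
_HIGHDIM_TRAINING = TrainingConfig(
    n_steps=3000, eval_every=250, learning_rate=1e-3,
    optimizer_kind="adam_prox", hidden_sizes=(64, 32), dtype=np.float32,
)
_COMPARATOR_TRAINING = TrainingConfig(
    n_steps=4500, eval_every=500, learning_rate=1e-3,
    optimizer_kind="adam_prox", hidden_sizes=(32, 16), dtype=np.float32,
)


@dataclass(frozen=True)
class ExperimentSpec:
    name: str  # fig2_trace | fig3_grid | fig3_groupsize | fig4_cph_compare
    sim_config: SimulationConfig | None = None
    training: TrainingConfig | None = None
    scale_grid: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0)
    alpha_grid: tuple[float, ...] = (0.9, 0.99)
    group_sizes: tuple[int, ...] = (1, 2, 4, 8, 16)  # fig3_groupsize arms
    n_relevant_features: int = 16  # held fixed across group-size arms
    replicates: int = 5
    seed: int = 0
    group_lasso_scale: float | None = None  # per-experiment default below
    group_lasso_alpha: float = 0.99
    lasso_scale: float = 2.5  # singleton-group (feature-wise) arm
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.name not in ("fig2_trace", "fig3_grid", "fig3_groupsize", "fig4_cph_compare"):
            raise ValueError(f"unknown experiment {self.name!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.sim_config is None:
            base = COMPARATOR_CONFIG if self.name == "fig4_cph_compare" else S1_CONFIG
            object.__setattr__(self, "sim_config", base)
        if self.training is None:
            tr = _COMPARATOR_TRAINING if self.name == "fig4_cph_compare" else _HIGHDIM_TRAINING
            object.__setattr__(self, "training", tr)
        if self.group_lasso_scale is None:
            # low-dimensional comparator runs want a gentler penalty
            object.__setattr__(
                self, "group_lasso_scale", 0.25 if self.name == "fig4_cph_compare" else 2.0
            )


def _manifest(outdir: Path, spec: ExperimentSpec) -> None:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, type):
            return o.__name__
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    payload = {"spec": dataclasses.asdict(spec), "version": __version__}
    (outdir / "manifest.json").write_text(json.dumps(payload, default=enc, indent=2))


def _regimes(spec: ExperimentSpec, group_map) -> dict[str, RegularizationConfig]:
    # the lasso regime is feature-wise selection: every feature its own
    # group (p_l = 1), which is what the group penalty reduces to at
    # group size 1
    singleton = np.arange(len(group_map))
    return {
        "group_lasso": RegularizationConfig(
            scale=spec.group_lasso_scale, alpha=spec.group_lasso_alpha, group_map=group_map
        ),
        "lasso": RegularizationConfig(
            scale=spec.lasso_scale, alpha=spec.group_lasso_alpha, group_map=singleton
        ),
        "none": RegularizationConfig(scale=0.0, alpha=0.5, group_map=group_map),
    }


def _plot_traces(traces: dict[str, pd.DataFrame], path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(traces), figsize=(5 * len(traces), 4), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, (name, tr) in zip(axes, traces.items()):
        for part in ("train", "validation", "test"):
            ax.plot(tr["step"], tr[part], label=part)
        ax.set_title(name)
        ax.set_xlabel("training step")
        ax.set_ylim(0.3, 1.0)
    axes[0].set_ylabel("c-index")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _run_fig2(spec: ExperimentSpec, outdir: Path) -> dict:
    ds, _ = simulate(replace(spec.sim_config, rng_seed=spec.seed))
    splits = split(ds.n_samples, seed=spec.seed)
    traces = {}
    rows = []
    for name, reg in _regimes(spec, ds.group_map).items():
        _, trace = train(ds, reg, spec.training, splits=splits)
        traces[name] = trace
        t = trace.assign(regularization=name)
        rows.append(t)
    long = pd.concat(rows, ignore_index=True).melt(
        id_vars=["step", "regularization"],
        value_vars=["train", "validation", "test"],
        var_name="split",
        value_name="c_index",
    )
    long.to_csv(outdir / "trace.tsv", sep="\t", index=False)
    if spec.make_plots:
        _plot_traces(traces, outdir / "trace.png")
    final = {k: {p: float(tr[p].iloc[-1]) for p in ("train", "validation", "test")}
             for k, tr in traces.items()}
    return {"final_cindex": final}


def _run_fig3_grid(spec: ExperimentSpec, outdir: Path) -> dict:
    per_rep = []
    tables = []
    for r in range(spec.replicates):
        seed = spec.seed + r
        ds, _ = simulate(replace(spec.sim_config, rng_seed=seed))
        splits = split(ds.n_samples, seed=seed)
        tcfg = replace(spec.training, rng_seed=seed)
        rep: dict = {"replicate": r}
        singleton = np.arange(ds.n_features)
        for arm, alphas, gmap in (
            ("group_lasso", spec.alpha_grid, ds.group_map),
            ("lasso", (spec.group_lasso_alpha,), singleton),
        ):
            reg0 = RegularizationConfig(scale=1.0, alpha=alphas[0], group_map=gmap)
            table, best = grid_search(
                ds, reg0, tcfg, scale_grid=spec.scale_grid, alpha_grid=alphas,
                splits=splits, select="best_validation",
            )
            tables.append(table.assign(arm=arm, replicate=r))
            reg_best = RegularizationConfig(
                scale=best["scale"], alpha=best["alpha"], group_map=gmap
            )
            mdl, trace = train(ds, reg_best, tcfg, splits=splits)
            ix = int(trace["validation"].idxmax())  # best-validation-step selection
            rep[f"{arm}_scale"] = best["scale"]
            rep[f"{arm}_alpha"] = best["alpha"]
            rep[f"{arm}_val"] = best["validation_cindex"]
            rep[f"{arm}_test"] = float(trace.loc[ix, "test"])
        reg_none = RegularizationConfig(scale=0.0, alpha=0.5, group_map=ds.group_map)
        _, trace = train(ds, reg_none, tcfg, splits=splits)
        rep["none_test"] = float(trace["test"].iloc[-1])
        per_rep.append(rep)
    reps = pd.DataFrame(per_rep)
    reps.to_csv(outdir / "replicates.tsv", sep="\t", index=False)
    pd.concat(tables, ignore_index=True).to_csv(outdir / "grid.tsv", sep="\t", index=False)
    res = {}
    if spec.replicates >= 2:
        for a, b in (("group_lasso", "lasso"), ("group_lasso", "none"), ("lasso", "none")):
            w = compare_methods(reps[f"{a}_test"], reps[f"{b}_test"], sided="two")
            res[f"{a}_vs_{b}_p"] = w.p_value
    res["mean_val"] = {a: float(reps[f"{a}_val"].mean()) for a in ("group_lasso", "lasso")}
    return res


def _groupsize_sim(spec: ExperimentSpec, gs: int, seed: int) -> SimulationConfig:
    base = spec.sim_config
    n_features = base.n_groups * base.group_size
    if n_features % gs:
        raise ValueError(f"total features {n_features} not divisible by group size {gs}")
    if spec.n_relevant_features % gs:
        raise ValueError(f"{spec.n_relevant_features} relevant features not divisible by {gs}")
    return replace(
        base,
        n_groups=n_features // gs,
        group_size=gs,
        n_relevant_groups=spec.n_relevant_features // gs,
        rng_seed=seed,
    )


def _run_fig3_groupsize(spec: ExperimentSpec, outdir: Path) -> dict:
    rows = []
    for gs in spec.group_sizes:
        for r in range(spec.replicates):
            seed = spec.seed + r
            cfg = _groupsize_sim(spec, gs, seed)
            ds, _ = simulate(cfg)
            splits = split(ds.n_samples, seed=seed)
            reg = RegularizationConfig(
                scale=spec.group_lasso_scale, alpha=spec.group_lasso_alpha, group_map=ds.group_map
            )
            _, trace = train(ds, reg, replace(spec.training, rng_seed=seed), splits=splits)
            rows.append({"group_size": gs, "replicate": r,
                         "test_cindex": float(trace["test"].iloc[-1])})
    tbl = pd.DataFrame(rows)
    tbl.to_csv(outdir / "groupsize.tsv", sep="\t", index=False)
    res: dict = {"mean_by_group_size": tbl.groupby("group_size")["test_cindex"].mean().to_dict()}
    if spec.replicates >= 2:
        arm1 = tbl.query("group_size == 1")["test_cindex"]
        for gs in spec.group_sizes:
            if gs == 1 or len(tbl.query("group_size == @gs")) < 2:
                continue
            w = compare_methods(tbl.query("group_size == @gs")["test_cindex"], arm1, sided="one")
            res[f"p_size{gs}_gt_size1"] = w.p_value
    return res


def _run_fig4(spec: ExperimentSpec, outdir: Path) -> dict:
    rows = []
    for link in ("identity", "quadratic", "absolute"):
        for r in range(spec.replicates):
            seed = spec.seed + r
            cfg = replace(spec.sim_config, link=link, rng_seed=seed)
            ds, _ = simulate(cfg)
            splits = split(ds.n_samples, seed=seed)
            reg = RegularizationConfig(
                scale=spec.group_lasso_scale, alpha=spec.group_lasso_alpha, group_map=ds.group_map
            )
            mdl, trace = train(ds, reg, replace(spec.training, rng_seed=seed), splits=splits)
            cph_c, _ = fit_cph_baseline(ds.subset(splits.train), ds.subset(splits.test))
            rows.append({"link": link, "replicate": r,
                         "gdp": float(trace["test"].iloc[-1]), "cph": cph_c})
    tbl = pd.DataFrame(rows)
    tbl.to_csv(outdir / "cph_compare.tsv", sep="\t", index=False)
    res = {}
    for link in ("identity", "quadratic", "absolute"):
        sub = tbl.query("link == @link")
        entry = {"gdp_mean": float(sub["gdp"].mean()), "cph_mean": float(sub["cph"].mean())}
        if spec.replicates >= 2:
            sided = "two" if link == "identity" else "one"
            w = compare_methods(sub["gdp"], sub["cph"], sided=sided)
            entry["p_value"] = w.p_value
            entry["sided"] = sided
        res[link] = entry
    return res


_RUNNERS = {
    "fig2_trace": _run_fig2,
    "fig3_grid": _run_fig3_grid,
    "fig3_groupsize": _run_fig3_groupsize,
    "fig4_cph_compare": _run_fig4,
}


def run_experiment(spec: ExperimentSpec, outdir: str | Path) -> dict:
    """Run one named experiment; writes tables/plots/manifest, returns summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _manifest(outdir, spec)
    summary = _RUNNERS[spec.name](spec, outdir)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary


# ---------------------------------------------------------------------------
# fixtures

def make_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write small deterministic datasets for tests and examples.

    (a) a 30-sample x 12-column mixed clinical/omics raw table with
    deliberate missingness (one column above the 80% missingness bar) and
    categorical columns, plus its column metadata; (b) a 100-sample
    simulated survival dataset with 40 features in 10 groups.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n = 30
    genes = ["TP53", "EGFR", "PTEN", "MYC"]
    cols: dict[str, object] = {}
    meta_rows = []
    for gene in genes:
        for layer in ("expr", "cnv"):
            name = f"{gene}_{layer}"
            x = rng.normal(size=n)
            miss = rng.random(n) < 0.15
            x = np.where(miss, np.nan, x)
            cols[name] = x
            meta_rows.append({"column": name, "type": "numeric", "gene_id": gene, "layer": layer})
    # a column failing the 80% missingness bar
    bad = rng.normal(size=n)
    bad[: int(np.ceil(0.85 * n))] = np.nan
    cols["TP53_protein"] = bad
    meta_rows.append({"column": "TP53_protein", "type": "numeric", "gene_id": "TP53", "layer": "protein"})
    cols["age"] = rng.integers(40, 85, n).astype(float)
    meta_rows.append({"column": "age", "type": "numeric", "gene_id": "", "layer": "clinical"})
    stage = rng.choice(["I", "II", "III"], n)
    stage_missing = rng.random(n) < 0.1
    cols["stage"] = np.where(stage_missing, None, stage)
    meta_rows.append({"column": "stage", "type": "categorical", "gene_id": "", "layer": "clinical"})
    cols["sex"] = rng.choice(["F", "M"], n)
    meta_rows.append({"column": "sex", "type": "categorical", "gene_id": "", "layer": "clinical"})

    raw = pd.DataFrame(cols, index=pd.Index([f"P{i:03d}" for i in range(n)], name="sample_id"))
    paths = {"raw_table": outdir / "raw_table.tsv", "raw_meta": outdir / "raw_meta.tsv"}
    raw.to_csv(paths["raw_table"], sep="\t", float_format="%.6g")
    pd.DataFrame(meta_rows).to_csv(paths["raw_meta"], sep="\t", index=False)

    cfg = SimulationConfig(
        n_samples=100, n_groups=10, group_size=4, n_relevant_groups=3, rng_seed=seed
    )
    ds, truth = simulate(cfg)
    paths.update(write_dataset(ds, outdir, prefix="survival_small", truth=truth))
    return paths
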