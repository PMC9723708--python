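"""End-to-end orchestration: simulate/load -> rarefy -> phases ->
assembly -> DOC -> ecological groups -> removal statistics.

A single :class:`RunConfig` (either an embedded simulation config or a
set of input paths) drives every stage; one seed propagates to each
stochastic step, so a run is reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly, community, copynum, doc, ecogroups, io, synthio
from .errors import ValidationError


@dataclass
class RunConfig:
    """Inputs and stage parameters for one full analysis run.

    Exactly one of ``sim`` (embedded simulation) or ``inputs`` (paths to
    table/metadata/tree/chem/copy-number files) must be provided.
    """

    sim: synthio.SimConfig | None = None
    inputs: dict[str, str] | None = None
    rarefaction_depth: int | None = None   # None -> smallest library size
    n_null: int = 999
    n_boot: int = 1000
    k_phases: int = 3
    alpha: float = 0.05
    prevalence_min: float = 0.1
    pseudocount: float = 0.5   # for size factors on sparse tables
    control_label: str = "Control"
    convention: str = "framework"
    phases: dict[str, int] | None = None   # override clustering if given
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ValidationError(
                "exactly one of sim / inputs must be provided")


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    sim = raw.pop("sim", None)
    if sim is not None:
        treatments = sim.pop("treatments", None)
        if treatments is not None:
            sim["treatments"] = [synthio.Treatment(t["name"],
                                                   dict(t.get("compounds", {})))
                                 for t in treatments]
        sim = synthio.SimConfig(**sim)
    return RunConfig(sim=sim, **raw)


def _load_inputs(cfg: RunConfig):
    paths = cfg.inputs
    required = ("table", "metadata", "tree", "chem", "copy_numbers")
    missing = [k for k in required if k not in paths]
    if missing:
        raise ValidationError(f"missing input paths: {missing}")
    table = io.read_community(paths["table"], paths["metadata"])
    tree = io.read_tree(paths["tree"])
    chem = io.read_chem(paths["chem"])
    cn = io.read_copy_numbers(paths["copy_numbers"])
    return table, tree, chem, cn, None


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage in dependency order and return the report.

    The report is a plain JSON-serializable dictionary; identical
    config + seed gives a byte-identical serialized report.
    """
    ss = np.random.SeedSequence(cfg.seed)
    seeds = {name: int(c.generate_state(1)[0] % (2**31))
             for name, c in zip(
                 ["rarefy", "copynum", "assembly", "doc"], ss.spawn(4))}
    stage = "load"
    try:
        if cfg.sim is not None:
            table, chem, truth = synthio.simulate_experiment(cfg.sim)
            # the experiment derives its tree deterministically from the
            # simulation seed; regenerate the identical tree here
            tree = synthio.simulate_tree(cfg.sim.n_otus, _sim_tree_seed(cfg.sim))
            cn = synthio.simulate_copy_numbers(
                tree, seeds["copynum"], unassigned_fraction=0.05)
        else:
            table, tree, chem, cn, truth = _load_inputs(cfg)

        stage = "rarefy"
        totals = table.counts.sum(axis=1)
        depth = cfg.rarefaction_depth or int(totals.min())
        low = totals.index[totals < depth].tolist()
        if low:
            raise ValidationError(
                f"samples below rarefaction depth {depth}: {low}")
        rarefied = community.rarefy(table, depth, seeds["rarefy"])

        stage = "removal"
        removal = community.removal_rate(chem)
        removal_stats = _removal_statistics(removal)

        stage = "phases"
        if cfg.phases is not None:
            phase_assign = copynum.PhaseAssignment(dict(cfg.phases))
        else:
            phase_assign = _cluster_phases(rarefied, cn, cfg)
        phases = phase_assign.mapping

        treatments = [t for t in rarefied.metadata["treatment"].unique()
                      if t != cfg.control_label]
        D = io.patristic_matrix(tree)

        stage = "assembly"
        assembly_report = {}
        for i, trt in enumerate(treatments):
            pf = assembly.process_fractions(
                rarefied, D, phases, trt, control_label=cfg.control_label,
                n_null=cfg.n_null, seed=seeds["assembly"] + i,
                convention=cfg.convention)
            assembly_report[trt] = {
                str(phase): {proc: float(pf.fractions.loc[phase, proc])
                             for proc in assembly.PROCESSES}
                for phase in pf.fractions.index}

        stage = "doc"
        doc_report = {}
        for i, trt in enumerate(treatments):
            res = doc.doc_analysis(rarefied, trt, n_boot=cfg.n_boot,
                                   seed=seeds["doc"] + i)
            doc_report[trt] = {
                "n_points": int(len(res.points)),
                "cutoff": res.cutoff,
                "slope": res.slope,
                "fraction_negative": res.fraction_negative,
                "n_boot": res.n_boot,
            }

        stage = "groups"
        groups_report = {}
        for trt in treatments:
            calls = ecogroups.classify_otus(
                rarefied, phase_assign, trt, alpha=cfg.alpha,
                prevalence_min=cfg.prevalence_min,
                pseudocount=cfg.pseudocount)
            counts = ecogroups.category_counts(calls)
            groups_report[trt] = {k: int(v) for k, v in counts.items()}

        stage = "turnover"
        turnover_report = {}
        for trt in treatments:
            ts = community.turnover_regression(rarefied, trt,
                                               control_label=cfg.control_label)
            turnover_report[trt] = {"slope": ts.slope,
                                    "slope_pvalue": ts.slope_pvalue}
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    return {
        "seed": cfg.seed,
        "n_samples": int(len(table.sample_ids)),
        "rarefaction_depth": depth,
        "phases": {b: int(p) for b, p in sorted(phases.items())},
        "removal": removal_stats,
        "assembly": assembly_report,
        "doc": doc_report,
        "groups": groups_report,
        "turnover": turnover_report,
    }


def _sim_tree_seed(sim_cfg: synthio.SimConfig) -> int:
    child = np.random.SeedSequence(sim_cfg.seed).spawn(1)[0]
    return int(child.generate_state(1)[0] % (2**31))


def _cluster_phases(table, cn, cfg: RunConfig) -> copynum.PhaseAssignment:
    treated = table.subset_samples(
        [s for s in table.sample_ids
         if table.metadata.loc[s, "treatment"] != cfg.control_label])
    wm = copynum.sample_copy_numbers(treated, cn)
    md = treated.metadata
    profile = pd.DataFrame({
        "batch": md["batch"],
        "microcosm": md["treatment"].astype(str) + "_r"
        + md["replicate"].astype(str),
        "wm": wm,
    }).pivot_table(index="batch", columns="microcosm", values="wm")
    return copynum.phase_clustering(profile, k=cfg.k_phases)


def _removal_statistics(removal: pd.DataFrame) -> dict:
    """Mean removal per treatment arm/compound plus the test contracts."""
    removal = removal.copy()
    removal["treatment"] = removal["microcosm_id"].str.rsplit(
        "_r", n=1).str[0]
    out = {}
    for (trt, compound), grp in removal.groupby(["treatment", "compound"]):
        batches = io.sort_batches(grp["batch"])
        consecutive = {}
        for b1, b2 in zip(batches, batches[1:]):
            a = grp.loc[grp["batch"] == b1, "removal_percent"].to_numpy()
            b = grp.loc[grp["batch"] == b2, "removal_percent"].to_numpy()
            _, p = community.rank_sum_test(a, b)
            consecutive[f"{b1}-{b2}"] = p
        out.setdefault(trt, {})[compound] = {
            "mean_removal_percent": float(grp["removal_percent"].mean()),
            "sd_removal_percent": float(grp["removal_percent"].std(ddof=1)),
            "consecutive_batch_wilcoxon_p": consecutive,
        }
    # between-compound comparison within each mixture arm
    for trt, grp in removal.groupby("treatment"):
        compounds = sorted(grp["compound"].unique())
        if len(compounds) >= 2:
            groups = [grp.loc[grp["compound"] == c,
                              "removal_percent"].to_numpy()
                      for c in compounds]
            h, p = community.kruskal_wallis(groups)
            out[trt]["kruskal_wallis_between_compounds"] = {
                "H": h, "p": p}
    return out


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2))


def config_to_yaml(cfg: RunConfig, path) -> None:
    raw = dataclasses.asdict(cfg)
    if raw.get("sim") is not None:
        raw["sim"]["treatments"] = [
            {"name": t["name"], "compounds": t["compounds"]}
            for t in raw["sim"]["treatments"]]
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))
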