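"""End-to-end study workflow.

``run_pipeline`` executes, over a supplied or simulated multilocus
alignment: concatenation -> site/indel catalogue -> per-group pi ->
Dxy/Fst/Kst with permutation tests -> sliding-window divergence -> NJ +
bootstrap per region (5'-COI, 3'-COI, full COI, concatenate) -> RF
discordance -> triplet recombination search -> segment contrast table.  All
artifacts land in the output directory with a manifest recording inputs,
parameters, per-stage seeds and status; independent stages continue after a
stage error.
"""

from __future__ import annotations

import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import divergence, differentiation, recombination, trees, variation
from .alignment import (
    Alignment,
    GroupAssignment,
    PartitionMap,
    concatenate,
    read_fasta_alignment,
)
from .contrast import segment_divergence_table
from .divergence import WindowSpec, profile_frame
from .errors import ConfigError
from .simulate import SimulationConfig, simulate_two_lineages, write_simulation
from .util import substream


@dataclass
class RunConfig:
    """Pipeline configuration (see ``RunConfig.from_yaml``)."""

    output_dir: str
    seed: int = 0
    # either a simulate block ...
    simulate: SimulationConfig | None = None
    # ... or explicit inputs
    fasta: dict[str, str] | None = None  # partition name -> path
    partitions_tsv: str | None = None
    groups_tsv: str | None = None
    # analysis parameters
    group_a: list[str] = field(default_factory=lambda: ["TYP"])
    group_b: list[str] = field(default_factory=lambda: ["SHA"])
    model: str = "p"
    n_perm: int = 1000
    bootstrap_reps: int = 1000
    recomb_n_perm: int = 4999
    window_concat: WindowSpec = field(default_factory=lambda: WindowSpec(100, 1))
    window_region: WindowSpec = field(default_factory=lambda: WindowSpec(50, 10))
    focal_region: str = "COI"
    region_split: int = 740
    run_recombination: bool = True
    run_trees: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        kwargs: dict[str, Any] = {}
        for key in (
            "output_dir", "seed", "group_a", "group_b", "model", "n_perm",
            "bootstrap_reps", "recomb_n_perm", "focal_region", "region_split",
            "run_recombination", "run_trees", "partitions_tsv", "groups_tsv",
            "fasta",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "output_dir" not in kwargs:
            raise ConfigError("config requires output_dir")
        for wkey, attr in (("window_concat", "window_concat"),
                           ("window_region", "window_region")):
            if wkey in raw:
                kwargs[attr] = WindowSpec(**raw[wkey])
        if "simulate" in raw and raw["simulate"] is not None:
            sim = raw["simulate"]
            if sim == "default" or sim is True:
                kwargs["simulate"] = SimulationConfig(seed=raw.get("seed", 0))
            else:
                from .simulate import IndelSpec, PartitionSpec, RecombinantSpec

                sim_kwargs = dict(sim)
                if "partitions" in sim_kwargs:
                    sim_kwargs["partitions"] = [
                        PartitionSpec(**p) for p in sim_kwargs["partitions"]
                    ]
                if "fixed_indels" in sim_kwargs:
                    sim_kwargs["fixed_indels"] = [
                        IndelSpec(**i) for i in sim_kwargs["fixed_indels"]
                    ]
                if "recombinants" in sim_kwargs:
                    sim_kwargs["recombinants"] = [
                        RecombinantSpec(**r) for r in sim_kwargs["recombinants"]
                    ]
                sim_kwargs.setdefault("seed", raw.get("seed", 0))
                kwargs["simulate"] = SimulationConfig(**sim_kwargs)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            if not (self.fasta and self.partitions_tsv and self.groups_tsv):
                raise ConfigError(
                    "config needs either a simulate block or fasta + "
                    "partitions_tsv + groups_tsv"
                )
            missing = [p for p in [*self.fasta.values(), self.partitions_tsv,
                                   self.groups_tsv] if not Path(p).exists()]
            if missing:
                raise ConfigError(f"input files missing: {missing}")


class _Manifest:
    def __init__(self, out: Path, config: RunConfig):
        self.path = out / "manifest.json"
        self.doc: dict[str, Any] = {
            "seed": config.seed,
            "model": config.model,
            "n_perm": config.n_perm,
            "bootstrap_reps": config.bootstrap_reps,
            "stages": {},
        }

    def record(self, stage: str, status: str, seconds: float,
               seed: int | None = None, error: str | None = None) -> None:
        entry: dict[str, Any] = {"status": status, "seconds": round(seconds, 3)}
        if seed is not None:
            entry["seed"] = seed
        if error:
            entry["error"] = error
        self.doc["stages"][stage] = entry
        self.path.write_text(json.dumps(self.doc, indent=2) + "\n")


def _load_inputs(config: RunConfig, out: Path):
    if config.simulate is not None:
        aln, pm, groups, truth = simulate_two_lineages(config.simulate)
        write_simulation(out / "simulated", aln, pm, groups, truth)
        return aln, pm, groups
    alns = [(name, read_fasta_alignment(path))
            for name, path in config.fasta.items()]
    aln, pm = concatenate(alns, id_policy="strict")
    groups = GroupAssignment.read_tsv(config.groups_tsv)
    groups.check_covers(aln)
    want = PartitionMap.read_tsv(config.partitions_tsv)
    if want.entries != pm.entries:
        raise ConfigError("partition file disagrees with concatenated lengths")
    return aln, pm, groups


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every stage; returns the summary dict also written as JSON."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config)
    summary: dict[str, Any] = {}

    t0 = time.perf_counter()
    aln, pm, groups = _load_inputs(config, out)
    manifest.record("load", "ok", time.perf_counter() - t0)

    ids_a = groups.members(*config.group_a)
    ids_b = groups.members(*config.group_b)
    analysed = ids_a + ids_b
    core = aln.subset(analysed)
    rec_ids = [i for i in aln.ids if i not in analysed]

    def stage(name: str, fn, seeded: bool = False):
        t = time.perf_counter()
        seed = substream(config.seed, name) if seeded else None
        try:
            result = fn(seed) if seeded else fn()
            manifest.record(name, "ok", time.perf_counter() - t, seed=seed)
            return result
        except Exception as exc:  # independent stages continue
            manifest.record(
                name, "error", time.perf_counter() - t, seed=seed,
                error=f"{type(exc).__name__}: {exc}",
            )
            summary.setdefault("errors", []).append(
                {"stage": name, "error": str(exc),
                 "trace": traceback.format_exc(limit=3)}
            )
            return None

    # --- site and indel catalogue -------------------------------------
    def _sites():
        cat = variation.segregating_sites(core, groups=groups)
        cat.to_frame().to_csv(out / "segregating_sites.tsv", sep="\t", index=False)
        fixed = variation.fixed_differences(core, ids_a, ids_b)
        events = variation.indel_events(core, reference_id=core.ids[0])
        fixed_ind = variation.fixed_indels(events, ids_a, ids_b)
        variation.indel_table(events).to_csv(out / "indels.tsv", sep="\t",
                                             index=False)
        return {
            "segregating_sites": len(cat.positions),
            "fixed_differences": len(fixed),
            "indel_events": len(events),
            "fixed_indels": len(fixed_ind),
        }

    res = stage("site_catalogue", _sites)
    if res:
        summary.update(res)

    # --- diversity ----------------------------------------------------
    def _pi():
        return {
            "pi_group_a": variation.nucleotide_diversity(core, ids_a).pi
            if len(ids_a) >= 2 else None,
            "pi_group_b": variation.nucleotide_diversity(core, ids_b).pi
            if len(ids_b) >= 2 else None,
        }

    res = stage("diversity", _pi)
    if res:
        summary.update(res)

    # --- divergence + differentiation ---------------------------------
    def _dxy(seed):
        total = divergence.dxy(core, ids_a, ids_b, model=config.model,
                               bootstrap_reps=config.bootstrap_reps, seed=seed)
        per_part = {}
        for name in pm.names:
            lo, hi = pm.interval(name)
            region = core.slice(lo, hi)
            per_part[name] = divergence.dxy(
                region, ids_a, ids_b, model=config.model,
                bootstrap_reps=config.bootstrap_reps, seed=seed,
            ).dxy
        return {"dxy_total": total.dxy, "dxy_se": total.se,
                "dxy_per_partition": per_part}

    res = stage("dxy", _dxy, seeded=True)
    if res:
        summary.update(res)

    def _diff(seed):
        fst = differentiation.permutation_test(
            core, ids_a, ids_b, "Fst", config.n_perm, seed)
        kst_res = differentiation.permutation_test(
            core, ids_a, ids_b, "Kst", config.n_perm, seed)
        return {
            "fst": fst.value, "fst_p": fst.p_value,
            "kst": kst_res.value, "kst_p": kst_res.p_value,
        }

    res = stage("differentiation", _diff, seeded=True)
    if res:
        summary.update(res)

    # --- sliding windows ----------------------------------------------
    def _windows():
        prof = divergence.sliding_window_divergence(
            core, ids_a, ids_b, config.window_concat, model=config.model)
        profile_frame(prof).to_csv(out / "windows_concatenate.tsv", sep="\t",
                                   index=False)
        lo, hi = pm.interval(config.focal_region)
        region = core.slice(lo, hi)
        prof_r = divergence.sliding_window_divergence(
            core.slice(lo, hi), ids_a, ids_b, config.window_region,
            model=config.model)
        profile_frame(prof_r).to_csv(
            out / f"windows_{config.focal_region}.tsv", sep="\t", index=False)
        return {"windows_concat": int(prof.values.size),
                "windows_region": int(prof_r.values.size)}

    res = stage("windows", _windows)
    if res:
        summary.update(res)

    # --- trees + discordance ------------------------------------------
    if config.run_trees:
        def _trees(seed):
            lo, hi = pm.interval(config.focal_region)
            split_abs = lo + config.region_split - 1
            regions = {
                "concatenate": (1, aln.length),
                f"{config.focal_region}_full": (lo, hi),
                f"{config.focal_region}_5prime": (lo, split_abs),
                f"{config.focal_region}_3prime": (split_abs + 1, hi),
            }
            built: dict[str, trees.Tree] = {}
            for name, (a, b) in regions.items():
                tr = trees.bootstrap_support(
                    aln.slice(a, b), model=config.model,
                    n_reps=config.bootstrap_reps, seed=seed)
                trees.write_newick(tr, out / f"tree_{name}.nwk")
                built[name] = tr
            rf = trees.robinson_foulds(
                built[f"{config.focal_region}_5prime"],
                built[f"{config.focal_region}_3prime"])
            info = {"rf_5prime_vs_3prime": rf}
            if rec_ids:
                r = rec_ids[0]
                for side in ("5prime", "3prime"):
                    dists = trees.leaf_distances(
                        built[f"{config.focal_region}_{side}"], r)
                    nn = min(dists, key=dists.get)
                    info[f"recomb_nearest_{side}"] = nn
                    info[f"recomb_nearest_{side}_group"] = groups.group_of(nn)
            return info

        res = stage("trees", _trees, seeded=True)
        if res:
            summary.update(res)

    # --- recombination -------------------------------------------------
    if config.run_recombination:
        def _recomb(seed):
            lo, hi = pm.interval(config.focal_region)
            # one representative per group plus every ungrouped sequence:
            # near-identical within-group samples add no signal but inflate
            # the Bonferroni family
            reps = [groups.members(g)[0]
                    for g in (*config.group_a, *config.group_b)
                    if groups.members(g)]
            region = aln.subset(dict.fromkeys(reps + rec_ids)).slice(lo, hi)
            events = recombination.triplet_search(
                region, n_perm=config.recomb_n_perm, seed=seed)
            recombination.events_frame(events).to_csv(
                out / "recombination_events.tsv", sep="\t", index=False)
            return {"recombination_events": [
                {"recombinant": e.recombinant, "major": e.major_parent,
                 "minor": e.minor_parent, "begin": e.begin, "end": e.end,
                 "segment_length": e.segment_length,
                 "p_corrected": e.p_corrected}
                for e in events]}

        res = stage("recombination", _recomb, seeded=True)
        if res:
            summary.update(res)

    # --- segment contrast ----------------------------------------------
    def _contrast(seed):
        lo, hi = pm.interval(config.focal_region)
        region = aln.slice(lo, hi)
        focal = rec_ids[0] if rec_ids else region.ids[0]
        others = [i for i in region.ids if i != focal]
        table = segment_divergence_table(
            region, focal, others, split=config.region_split,
            model=config.model, bootstrap_reps=min(config.bootstrap_reps, 200),
            seed=seed)
        table.to_csv(out / "segment_divergence.tsv", sep="\t", index=False)
        return {"segment_table_rows": len(table)}

    res = stage("contrast", _contrast, seeded=True)
    if res:
        summary.update(res)

    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
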