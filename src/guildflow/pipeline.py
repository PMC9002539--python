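"""End-to-end pipeline orchestration.

Runs simulate/load -> rarefy -> alpha & beta diversity -> PCoA/aPCoA ->
PERMANOVA (four contrasts: NT vs ST at each timepoint, pre vs post within
each taster group) -> guild construction and comparisons -> mixed-model
associations -> per-group correlation networks, writing every artifact plus
a JSON run report into an output directory. All randomness derives from the
config seed through named substreams, so a fixed config reproduces its
outputs bit for bit (timings aside).
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
import yaml

from . import __version__
from .associations import build_network, lmm_associate, network_summary
from .diversity import DistanceMatrix, alpha_diversity_table, rarefy, unifrac
from .guilds import (
    compare_guilds,
    guild_abundance,
    guild_cluster,
    prevalence_filter,
    rm_correlation_matrix,
    to_relative,
)
from .io import (
    read_count_table,
    read_design,
    read_newick_tree,
    read_phenotypes,
)
from .ordination import apcoa, pcoa, permanova
from .synthetic import SyntheticDataset, SyntheticScenario, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "parse_config", "dump_config", "run_pipeline"]

_GUILD_DEFAULTS = {"min_guild_size": 2, "r_threshold": None, "linkage": "average"}
_INPUT_KEYS = ("counts", "tree", "design", "proteins", "sensory")


@dataclass
class PipelineConfig:
    """Validated pipeline parameters.

    Either ``scenario`` (synthetic mode) or ``inputs`` (paths to counts.tsv,
    tree.nwk, design.tsv, proteins.tsv, sensory.tsv) must be set. The
    rarefaction depth defaults to the scenario read depth in synthetic mode
    and to 76,000 reads/sample for real data.
    """

    scenario: SyntheticScenario | None = None
    inputs: dict | None = None
    rarefaction_depth: int | None = None
    prevalence_threshold: float = 0.5
    guild: dict = field(default_factory=lambda: dict(_GUILD_DEFAULTS))
    q_threshold: float = 0.25
    n_permutations: int = 9999
    beta_on_rarefied: bool = True
    seed: int = 0
    outdir: str = "guildflow_out"

    def __post_init__(self) -> None:
        if self.scenario is None and self.inputs is None:
            self.scenario = SyntheticScenario(seed=self.seed)
        if not (0.0 < self.prevalence_threshold < 1.0):
            raise ValueError("prevalence_threshold must be in (0, 1)")
        if not (0.0 <= self.q_threshold <= 1.0):
            raise ValueError("q_threshold must be in [0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        unknown = set(self.guild) - set(_GUILD_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown guild parameter(s): {sorted(unknown)}")
        self.guild = {**_GUILD_DEFAULTS, **self.guild}

    @property
    def depth(self) -> int:
        if self.rarefaction_depth is not None:
            return self.rarefaction_depth
        if self.scenario is not None:
            return self.scenario.read_depth
        return 76_000

    def to_dict(self) -> dict:
        d = {
            "inputs": self.inputs,
            "rarefaction_depth": self.rarefaction_depth,
            "prevalence_threshold": self.prevalence_threshold,
            "guild": dict(sorted(self.guild.items())),
            "q_threshold": self.q_threshold,
            "n_permutations": self.n_permutations,
            "beta_on_rarefied": self.beta_on_rarefied,
            "seed": self.seed,
            "outdir": self.outdir,
        }
        if self.scenario is not None:
            sc = dataclasses.asdict(self.scenario)
            sc["dropout"] = [list(x) for x in self.scenario.dropout]
            d["scenario"] = dict(sorted(sc.items()))
        else:
            d["scenario"] = None
        return dict(sorted(d.items()))


_TOP_KEYS = {
    "scenario", "inputs", "rarefaction_depth", "prevalence_threshold",
    "guild", "q_threshold", "n_permutations", "beta_on_rarefied",
    "seed", "outdir",
}


def parse_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML config file; unknown keys are an error, missing keys take
    their documented defaults. An empty file yields the default config."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs: dict = {}
    if raw.get("scenario") is not None:
        sc = dict(raw["scenario"])
        valid = {f.name for f in dataclasses.fields(SyntheticScenario)}
        bad = set(sc) - valid
        if bad:
            raise ValueError(f"unknown scenario key(s): {sorted(bad)}")
        if "dropout" in sc:
            sc["dropout"] = tuple(tuple(x) for x in sc["dropout"])
        kwargs["scenario"] = SyntheticScenario(**sc)
    if raw.get("inputs") is not None:
        inp = dict(raw["inputs"])
        bad = set(inp) - set(_INPUT_KEYS)
        if bad:
            raise ValueError(f"unknown input key(s): {sorted(bad)}")
        kwargs["inputs"] = inp
    for key in _TOP_KEYS - {"scenario", "inputs"}:
        if key in raw:
            kwargs[key] = raw[key]
    for key, typ in (("prevalence_threshold", float), ("q_threshold", float),
                     ("n_permutations", int), ("seed", int)):
        if key in kwargs:
            try:
                kwargs[key] = typ(kwargs[key])
            except (TypeError, ValueError):
                raise ValueError(f"config key {key!r} must be a {typ.__name__}")
    return PipelineConfig(**kwargs)


def dump_config(config: PipelineConfig) -> str:
    """Canonical YAML form of a config (sorted keys)."""
    return yaml.safe_dump(config.to_dict(), sort_keys=True)


def _substream(seed: int, k: int) -> int:
    """Named integer substream of the master seed, kept below 2**31."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def _load_inputs(config: PipelineConfig) -> SyntheticDataset:
    inp = config.inputs
    missing = [k for k in _INPUT_KEYS if k not in inp]
    if missing:
        raise ValueError(f"inputs missing path(s): {missing}")
    counts = read_count_table(inp["counts"])
    tree = read_newick_tree(inp["tree"])
    design = read_design(inp["design"])
    design.check_covers(counts)
    return SyntheticDataset(
        counts=counts,
        tree=tree,
        design=design,
        proteins=read_phenotypes(inp["proteins"]),
        sensory=read_phenotypes(inp["sensory"]),
        truth={},
    )


def _subject_covariates(meta: pd.DataFrame) -> pd.DataFrame:
    """One-hot subject indicators (last subject dropped) for aPCoA."""
    dummies = pd.get_dummies(meta["subject_id"], prefix="subject", dtype=float)
    return dummies.iloc[:, :-1]


def _contrast_samples(meta: pd.DataFrame):
    """The four standard contrasts of the paired two-group design."""
    for tp in ("pre", "post"):
        sel = meta[meta["timepoint"] == tp]
        yield (f"NT_vs_ST_{tp}", list(sel.index),
               sel["taster_status"], "free", None)
    for grp in ("NT", "ST"):
        sel = meta[meta["taster_status"] == grp]
        yield (f"pre_vs_post_{grp}", list(sel.index),
               sel["timepoint"], "stratified_by_subject", sel["subject_id"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write artifacts + run_report.json to the config's
    output directory; returns the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "guildflow_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    timings: dict = {}

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    report["failed_stage"] = name
                    (outdir / "run_report.json").write_text(
                        json.dumps({**report, "timings_seconds": timings},
                                   indent=2, sort_keys=True, default=str)
                    )
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Stage()

    with stage("input"):
        if config.inputs is not None:
            dataset = _load_inputs(config)
        else:
            dataset = generate_dataset(config.scenario)
            dataset.write(outdir / "synthetic")
        meta = dataset.design.data.loc[dataset.counts.sample_ids]

    with stage("rarefy"):
        rarefied = rarefy(dataset.counts, config.depth, _substream(config.seed, 1))
        rarefied.write(outdir / "rarefied_counts.tsv")
        meta = meta.loc[rarefied.sample_ids]

    with stage("alpha_diversity"):
        alpha = alpha_diversity_table(rarefied, tree=dataset.tree)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t", index=False)

    beta_table = rarefied if config.beta_on_rarefied else dataset.counts
    dms: dict[str, DistanceMatrix] = {}
    with stage("beta_diversity"):
        for name, weighted in (("unweighted_unifrac", False), ("weighted_unifrac", True)):
            dm = unifrac(beta_table, dataset.tree, weighted=weighted)
            dm.write(outdir / f"distance_{name}.tsv")
            dms[name] = dm

    with stage("ordination"):
        for name, dm in dms.items():
            res = pcoa(dm)
            _write_coords(res, outdir / f"pcoa_{name}.tsv")
            report["stages"].setdefault("ordination", {})[name] = {
                "proportion_explained_pc1": _pc_prop(res, 0),
                "proportion_explained_pc2": _pc_prop(res, 1),
            }
            for grp in ("NT", "ST"):
                sel = meta[meta["taster_status"] == grp].index
                sub = dm.subset(list(sel))
                adj = apcoa(sub, _subject_covariates(meta.loc[sel]))
                _write_coords(adj, outdir / f"apcoa_{name}_{grp}.tsv")

    with stage("permanova"):
        perm_out: dict = {}
        k = 10
        for cname, samples, groups, scheme, strata in _contrast_samples(meta):
            perm_out[cname] = {}
            for mname, dm in dms.items():
                sub = dm.subset(samples)
                res = permanova(
                    sub,
                    groups.loc[samples],
                    scheme=scheme,
                    strata=None if strata is None else strata.loc[samples],
                    n_permutations=config.n_permutations,
                    seed=_substream(config.seed, k),
                )
                k += 1
                perm_out[cname][mname] = res.to_dict()
        (outdir / "permanova.json").write_text(
            json.dumps(perm_out, indent=2, sort_keys=True)
        )
        report["stages"]["permanova"] = perm_out

    with stage("guilds"):
        prevalent, prevalence = prevalence_filter(
            rarefied, config.prevalence_threshold
        )
        prevalence.rename("prevalence").to_csv(outdir / "prevalence.tsv", sep="\t")
        rel = to_relative(rarefied, transform="arcsine_sqrt")
        rel_prev = rel.restrict(prevalent.asv_ids)
        subjects = meta["subject_id"]
        corr, _ = rm_correlation_matrix(rel_prev.data, subjects)
        corr.to_csv(outdir / "asv_rm_correlation.tsv", sep="\t")
        assignment = guild_cluster(rel_prev, subjects, **config.guild)
        assignment.to_frame().to_csv(outdir / "guild_assignment.tsv", sep="\t", index=False)
        (outdir / "guild_audit.json").write_text(
            json.dumps(list(assignment.audit), indent=2)
        )
        gtable = guild_abundance(rel, assignment)
        gtable.write(outdir / "guild_abundance.tsv")
        comparisons = []
        for tp in ("pre", "post"):
            c = compare_guilds(gtable, dataset.design, "NT_vs_ST", timepoint=tp)
            c.insert(0, "contrast", f"NT_vs_ST_{tp}")
            comparisons.append(c)
        for grp in ("NT", "ST"):
            c = compare_guilds(gtable, dataset.design, "pre_vs_post", group=grp)
            c.insert(0, "contrast", f"pre_vs_post_{grp}")
            comparisons.append(c)
        pd.concat(comparisons, ignore_index=True).to_csv(
            outdir / "guild_comparisons.tsv", sep="\t", index=False
        )
        prevalent_share = float(
            to_relative(rarefied).data[prevalent.asv_ids].to_numpy().sum(axis=1).mean()
        )
        report["stages"]["guilds"] = {
            "n_prevalent_asvs": prevalent.data.shape[1],
            "n_guilds": assignment.n_guilds,
            "n_unassigned": len(assignment.unassigned),
            "prevalent_mean_share_of_reads": prevalent_share,
        }

    with stage("associations"):
        assoc = pd.concat(
            [
                lmm_associate(gtable, dataset.proteins, dataset.design,
                              family="guild_protein"),
                lmm_associate(gtable, dataset.sensory, dataset.design,
                              family="guild_sensory"),
            ],
            ignore_index=True,
        )
        assoc.to_csv(outdir / "associations.tsv", sep="\t", index=False)
        report["stages"]["associations"] = {
            "n_fits": int(len(assoc)),
            "n_discoveries": int((assoc["q_value"] < config.q_threshold).sum()),
        }

    with stage("networks"):
        net_summaries = {}
        for grp in ("NT", "ST"):
            net = build_network(
                gtable, dataset.proteins, dataset.sensory, dataset.design,
                group=grp, q_threshold=config.q_threshold,
            )
            net.write_graphml(outdir / f"network_{grp}.graphml")
            net.write_edgelist(outdir / f"network_{grp}_edges.tsv")
            net_summaries[grp] = network_summary(net)
        (outdir / "network_summaries.json").write_text(
            json.dumps(net_summaries, indent=2, sort_keys=True)
        )
        report["stages"]["networks"] = net_summaries

    report_path = outdir / "run_report.json"
    report_path.write_text(
        json.dumps({**report, "timings_seconds": timings}, indent=2,
                   sort_keys=True, default=str)
    )
    return {**report, "timings_seconds": timings}


def _pc_prop(res, i: int) -> float:
    return float(res.proportion_explained[i]) if len(res.proportion_explained) > i else 0.0


def _write_coords(res, path: Path) -> None:
    frame = res.coordinates_frame()
    long = frame.reset_index(names="sample_id").melt(
        id_vars="sample_id", var_name="axis", value_name="value"
    )
    long.to_csv(path, sep="\t", index=False)
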