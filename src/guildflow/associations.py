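"""Guild-phenotype association and tripartite correlation networks.

Guild abundances (arcsine-sqrt scale) are related to salivary-protein and
sensory variables with a linear mixed model — a random intercept per subject
absorbs the paired design, with age, gender and BMI as fixed covariates.
Within-family Benjamini-Hochberg adjustment yields q-values, and edges with
q below a permissive discovery threshold (default 0.25, appropriate for an
exploratory pilot-scale screen) enter a per-taster-group network whose nodes
are guilds, proteins and sensory attributes. Guild-guild and
protein-sensory edges use repeated-measures correlation instead of the
mixed model. Isolated nodes are excluded; guild-guild edges are styled
dashed, all others solid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .guilds import GuildAbundanceTable, rm_correlation
from .io import PhenotypeTable, StudyDesign

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "CorrelationNetwork",
    "lmm_associate",
    "bh_adjust",
    "build_network",
    "network_summary",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class AssociationResult:
    guild_id: str
    variable: str
    family: str
    coefficient: float
    std_error: float
    p_value: float
    q_value: float = np.nan
    converged: bool = True


def _design_covariates(meta: pd.DataFrame) -> np.ndarray:
    """Standardized age/BMI and a binary gender indicator."""
    age = meta["age"].to_numpy(dtype=float)
    bmi = meta["bmi"].to_numpy(dtype=float)
    gender = (meta["gender"] == "M").to_numpy(dtype=float)

    def z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    return np.column_stack([z(age), gender, z(bmi)])


def lmm_associate(
    gtable: GuildAbundanceTable,
    phenotypes: PhenotypeTable,
    design: StudyDesign,
    family: str = "guild_phenotype",
) -> pd.DataFrame:
    """Per (guild, variable) mixed-model association.

    Fits transformed guild abundance ~ variable + age + gender + bmi with a
    subject random intercept; reports the variable's slope, Wald p-value and
    BH q-value (adjusted within this call's family). Zero-variance variables
    are skipped with a warning; non-convergent fits are flagged and excluded
    from the FDR family.
    """
    samples = [s for s in gtable.data.index if s in phenotypes.data.index]
    meta = design.data.loc[samples]
    cov = _design_covariates(meta)
    groups = meta["subject_id"].to_numpy()
    results: list[AssociationResult] = []
    for var in phenotypes.variables:
        v = phenotypes.data.loc[samples, var].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if np.nanstd(v) == 0:
            logger.warning("lmm_associate: %s has zero variance; skipped", var)
            continue
        v_sd = np.nanstd(v)
        for guild in gtable.guild_ids:
            y = gtable.data.loc[samples, guild].to_numpy(dtype=float)
            # standardize both sides for optimizer conditioning (the arcsine
            # abundance scale is ~2 orders below the covariates); the slope
            # is mapped back to raw units afterwards
            y_sd = y[ok].std()
            if y_sd == 0:
                results.append(
                    AssociationResult(guild, var, family, np.nan, np.nan, np.nan,
                                      converged=False)
                )
                continue
            ys = (y[ok] - y[ok].mean()) / y_sd
            vs = (v[ok] - v[ok].mean()) / v_sd
            exog = np.column_stack([np.ones(ok.sum()), vs, cov[ok]])
            fit = None
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(ys, exog, groups=groups[ok])
                # powell first: gradient-free, robust when the random-intercept
                # variance sits on the boundary (where lbfgs hits singular
                # score evaluations); both are deterministic
                for method in ("powell", "lbfgs"):
                    try:
                        fit = model.fit(reml=True, method=method, maxiter=300)
                    except (np.linalg.LinAlgError, ValueError):
                        fit = None
                        continue
                    if np.isfinite(fit.pvalues[1]):
                        break
            if fit is None or not np.isfinite(fit.pvalues[1]):
                logger.warning("lmm_associate: %s ~ %s did not converge", guild, var)
                results.append(
                    AssociationResult(guild, var, family, np.nan, np.nan, np.nan,
                                      converged=False)
                )
                continue
            scale = y_sd / v_sd
            results.append(
                AssociationResult(
                    guild_id=guild,
                    variable=var,
                    family=family,
                    coefficient=float(fit.params[1]) * scale,
                    std_error=float(fit.bse[1]) * scale,
                    p_value=float(np.clip(fit.pvalues[1], np.finfo(float).tiny, 1.0)),
                    converged=bool(fit.converged),
                )
            )
    df = pd.DataFrame([r.__dict__ for r in results])
    if df.empty:
        return df
    good = df["converged"] & df["p_value"].notna()
    if good.any():
        df.loc[good, "q_value"] = bh_adjust(df.loc[good, "p_value"])
    return df


# ---------------------------------------------------------------------------
# networks


@dataclass
class CorrelationNetwork:
    """Undirected typed graph of FDR-selected associations for one group."""

    graph: nx.Graph
    group: str

    def edge_frame(self) -> pd.DataFrame:
        rows = []
        for a, b, attr in self.graph.edges(data=True):
            rows.append(
                {
                    "node_a": a,
                    "type_a": self.graph.nodes[a]["type"],
                    "node_b": b,
                    "type_b": self.graph.nodes[b]["type"],
                    "r_or_beta": attr["weight"],
                    "q": attr["q"],
                    "sign": attr["sign"],
                    "style": attr["style"],
                }
            )
        return pd.DataFrame(
            rows,
            columns=["node_a", "type_a", "node_b", "type_b",
                     "r_or_beta", "q", "sign", "style"],
        )

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    def write_edgelist(self, path: str | Path) -> None:
        self.edge_frame().to_csv(path, sep="\t", index=False)


def _add_edges(edges: list, records, q_threshold: float) -> None:
    for rec in records:
        if np.isnan(rec["q"]) or rec["q"] >= q_threshold:
            continue
        edges.append(rec)


def build_network(
    gtable: GuildAbundanceTable,
    proteins: PhenotypeTable,
    sensory: PhenotypeTable,
    design: StudyDesign,
    group: str,
    q_threshold: float = 0.25,
) -> CorrelationNetwork:
    """Tripartite guild/protein/sensory network for one taster group.

    Guild-protein and guild-sensory edges come from the mixed model;
    protein-sensory and guild-guild edges from repeated-measures correlation.
    BH adjustment runs separately within each of the four pairing families,
    and only edges with q strictly below ``q_threshold`` are retained. Nodes
    without a retained edge are excluded.
    """
    meta = design.data
    samples = [s for s in gtable.data.index if meta.loc[s, "taster_status"] == group]
    if len(samples) == 0:
        raise ValueError(f"no samples for group {group}")
    sub_design = StudyDesign(meta.loc[samples])
    sub_g = GuildAbundanceTable(gtable.data.loc[samples])
    sub_p = PhenotypeTable(proteins.data.loc[[s for s in samples if s in proteins.data.index]])
    sub_s = PhenotypeTable(sensory.data.loc[[s for s in samples if s in sensory.data.index]])

    edges: list[dict] = []

    for phen, fam, ntype in ((sub_p, "guild_protein", "protein"),
                             (sub_s, "guild_sensory", "sensory")):
        assoc = lmm_associate(sub_g, phen, sub_design, family=fam)
        if not assoc.empty:
            _add_edges(
                edges,
                (
                    {
                        "a": row.guild_id, "ta": "guild",
                        "b": row.variable, "tb": ntype,
                        "weight": row.coefficient, "q": row.q_value,
                    }
                    for row in assoc.itertuples()
                    if row.converged and not np.isnan(row.q_value)
                ),
                q_threshold,
            )

    subjects = meta.loc[samples, "subject_id"]

    def rm_family(table_a: pd.DataFrame, table_b: pd.DataFrame,
                  type_a: str, type_b: str) -> None:
        pairs, ps = [], []
        cols_b = list(table_b.columns)
        for i, va in enumerate(table_a.columns):
            start = i + 1 if table_a is table_b else 0
            for vb in cols_b[start:]:
                x = table_a[va].to_numpy(dtype=float)
                y = table_b[vb].to_numpy(dtype=float)
                try:
                    res = rm_correlation(x, y, subjects)
                except ValueError:
                    continue
                if not res.valid:
                    continue
                pairs.append((va, type_a, vb, type_b, res.r))
                ps.append(res.p_value)
        if not ps:
            return
        qs = bh_adjust(ps)
        _add_edges(
            edges,
            (
                {"a": a, "ta": ta, "b": b, "tb": tb, "weight": r, "q": q}
                for (a, ta, b, tb, r), q in zip(pairs, qs)
            ),
            q_threshold,
        )

    rm_family(sub_p.data, sub_s.data, "protein", "sensory")
    rm_family(sub_g.data, sub_g.data, "guild", "guild")

    graph = nx.Graph(group=group, q_threshold=q_threshold)
    for e in edges:
        if e["a"] == e["b"]:
            continue
        graph.add_node(e["a"], type=e["ta"])
        graph.add_node(e["b"], type=e["tb"])
        style = "dashed" if (e["ta"] == "guild" and e["tb"] == "guild") else "solid"
        graph.add_edge(
            e["a"], e["b"],
            weight=float(e["weight"]),
            q=float(e["q"]),
            sign="+" if e["weight"] > 0 else "-",
            style=style,
        )
    if graph.number_of_edges() == 0:
        logger.info("build_network: no edges below q=%.3g for group %s",
                    q_threshold, group)
    return CorrelationNetwork(graph=graph, group=group)


def network_summary(net: CorrelationNetwork) -> dict:
    """Node/edge counts, counts by node type and sign, and per-node degree."""
    g = net.graph
    by_type: dict[str, int] = {}
    for _, t in g.nodes(data="type"):
        by_type[t] = by_type.get(t, 0) + 1
    signs = {"+": 0, "-": 0}
    for _, _, s in g.edges(data="sign"):
        signs[s] += 1
    return {
        "group": net.group,
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "nodes_by_type": by_type,
        "positive_edges": signs["+"],
        "negative_edges": signs["-"],
        "degree": {n: int(d) for n, d in g.degree()},
    }
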