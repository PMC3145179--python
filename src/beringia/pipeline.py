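"""Single-config orchestration of the full inference chain.

Stages run in dependency order: dating (phylogram -> node ages over the
method-by-rate grid) -> DEC range reconstruction and crossing counts ->
thermal-tolerance MCMC and ancestral states at the crossing nodes ->
paleocurve smoothing/calibration -> gateway trend and match tests.  A
machine-readable manifest records the config, seeds and output hashes so a
run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import clock, dec, gateway, paleo, thermal
from .simulate import fixture_polyommatus, sim_delta18o
from .trees import Phylogeny, TaxonTable, mrca, read_newick

__all__ = ["RunConfig", "ValidationError", "validate", "run_all"]


class ValidationError(ValueError):
    """Raised with the complete list of configuration problems."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid run configuration:\n" +
                         "\n".join(f"  - {p}" for p in self.problems))


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    ``use_fixture = true`` pulls trees and codings from the built-in genus
    backbone; otherwise explicit file paths are required.  The δ18O series is
    synthetic unless ``d18o_csv`` is given.
    """

    out_dir: str = "beringia_run"
    seed: int = 0
    use_fixture: bool = True
    tree_phylogram: Optional[str] = None
    tree_chronogram: Optional[str] = None
    ranges_csv: Optional[str] = None
    traits_csv: Optional[str] = None
    hostplants_csv: Optional[str] = None
    d18o_csv: Optional[str] = None
    clades: Dict[str, List[str]] = field(default_factory=dict)  # clade -> tip labels
    stages: List[str] = field(default_factory=lambda: [
        "dating", "dec", "thermal", "paleo", "gateway"])
    mcmc_preset: str = "desk"
    max_range_size: int = 2
    smoothing: float = 1.0
    window: int = 50
    anchors: List[Tuple[float, float]] = field(
        default_factory=lambda: list(paleo.DEFAULT_ANCHORS))

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        anchors = raw.pop("anchors", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in
                     {f.name for f in dataclasses.fields(cls)}})
        if anchors is not None:
            cfg.anchors = [tuple(a) for a in anchors]
        return cfg


def _load_inputs(config: RunConfig):
    if config.use_fixture:
        fx = fixture_polyommatus(seed=config.seed + 2011)
        clades = config.clades or {
            c: list(t) for c, t in
            zip(fx.reported_ages_ma,
                [["Pseudolucia", "Echinargus", "Hemiargus", "Cyclargus",
                  "Freyeria", "Plebejus_OW"],
                 ["Icaricia", "Plebulina", "Plebejus_OW"],
                 ["Lycaeides_idas_OW", "Lycaeides_melissa", "Lycaeides_idas_NW"],
                 ["Agriades_glandon_OW", "Agriades_glandon_NW"],
                 ["Vacciniina_optilete_OW", "Vacciniina_optilete_NW"]])}
        return (fx.phylogram, fx.chronogram, fx.area_codings, fx.tolerances,
                fx.hostplants, clades)
    phylo = read_newick(Path(config.tree_phylogram).read_text(), unit="subs/site")
    chrono = (read_newick(Path(config.tree_chronogram).read_text(), unit="Ma")
              if config.tree_chronogram else None)
    ranges = TaxonTable.from_csv(config.ranges_csv)
    traits = TaxonTable.from_csv(config.traits_csv)
    hosts = (TaxonTable.from_csv(config.hostplants_csv)
             if config.hostplants_csv else None)
    return phylo, chrono, ranges, traits, hosts, config.clades


def validate(config: RunConfig) -> List[str]:
    """Check the whole config; returns the (possibly empty) problem list."""
    problems: List[str] = []
    if not config.use_fixture:
        for attr in ("tree_phylogram", "ranges_csv", "traits_csv"):
            p = getattr(config, attr)
            if p is None:
                problems.append(f"{attr} is required when use_fixture is false")
            elif not Path(p).exists():
                problems.append(f"{attr} file not found: {p}")
        if problems:
            return problems
    unknown = [s for s in config.stages
               if s not in ("dating", "dec", "thermal", "paleo", "gateway")]
    for s in unknown:
        problems.append(f"unknown stage {s!r}")
    if "gateway" in config.stages:
        for dep in ("dating", "dec", "thermal", "paleo"):
            if dep not in config.stages:
                problems.append(
                    f"gateway stage requires the {dep!r} stage to run")
    try:
        phylo, chrono, ranges, traits, hosts, clades = _load_inputs(config)
    except Exception as exc:  # noqa: BLE001 — report, do not crash validation
        problems.append(f"inputs failed to load: {exc}")
        return problems
    tips = set(phylo.tip_labels)
    for name, table in (("ranges", ranges), ("traits", traits),
                        ("hostplants", hosts)):
        if table is None:
            continue
        keys = set(table.taxa)
        for t in sorted(tips - keys):
            problems.append(f"{name} table is missing taxon {t!r}")
        for t in sorted(keys - tips):
            problems.append(f"{name} table has unknown taxon {t!r}")
    if chrono is not None and chrono.length_unit != "Ma":
        problems.append("chronogram must carry branch lengths in Ma")
    if phylo.length_unit != "subs/site":
        problems.append("phylogram must carry branch lengths in subs/site")
    for clade, tip_list in (clades or {}).items():
        for t in tip_list:
            if t not in tips:
                problems.append(f"clade {clade!r} references unknown tip {t!r}")
    return problems


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> Dict[str, object]:
    """Execute the configured stages; returns the manifest dict.

    Outputs written under ``config.out_dir``: ages.csv, recon.json,
    thermal_samples.csv, curve.csv, events.csv, trend.json, match.csv,
    gateway.png and manifest.json.
    """
    problems = validate(config)
    if problems:
        raise ValidationError(problems)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "seed": config.seed,
        "stages": list(config.stages),
        "outputs": {},
        "config": {f.name: getattr(config, f.name)
                   for f in dataclasses.fields(config)},
    }
    phylo, chrono, ranges, traits, hosts, clades = _load_inputs(config)
    artifacts: Dict[str, Path] = {}

    stage = "dating"
    try:
        node_ids = {c: mrca(phylo, tips) for c, tips in clades.items()}
        ages_tbl = None
        if "dating" in config.stages:
            runs = []
            for cfg in clock.default_rate_grid():
                cfg = dataclasses.replace(cfg, smoothing=(
                    config.smoothing if cfg.method == "penalized_likelihood"
                    else None), seed=config.seed)
                if cfg.method == "strict":
                    runs.append(clock.strict_clock_ages(phylo, cfg))
                else:
                    runs.append(clock.pl_smooth_ages(phylo, cfg))
            ages_tbl = clock.mean_ages(runs, sorted(set(node_ids.values())))
            p = out / "ages.csv"
            ages_tbl.to_csv(p)
            artifacts["ages"] = p
            mean_all = clock.mean_ages(runs, range(phylo.n_nodes))
            dated = _chronogram_from_ages(phylo, mean_all["age_mean"].to_numpy())
        else:
            dated = chrono
        if dated is None:
            raise RuntimeError("no chronogram available (enable dating or "
                               "provide tree_chronogram)")

        stage = "dec"
        recon = None
        if "dec" in config.stages:
            model = dec.DECModel(dated, ranges, max_range_size=config.max_range_size)
            recon = model.fit()
            n_cross, cross = dec.count_crossings(recon, dec.OLD_WORLD, dec.NEW_WORLD)
            p = out / "recon.json"
            p.write_text(json.dumps({
                "d": recon.params.d, "e": recon.params.e,
                "loglik": recon.loglik,
                "n_ow_nw_crossings": n_cross,
                "events": [e.__dict__ for e in recon.events],
            }, indent=1))
            artifacts["recon"] = p

        stage = "thermal"
        anc = {}
        if "thermal" in config.stages:
            tmodel = thermal.ThermalModel(phylo, traits, model="B")
            tres = tmodel.fit_mcmc(thermal.MCMCConfig.preset(
                config.mcmc_preset, seed=config.seed))
            p = out / "thermal_samples.csv"
            tres.samples.to_csv(p, index_label="sample")
            artifacts["thermal_samples"] = p
            states = tres.ancestral_states(sorted(set(node_ids.values())))
            anc = {s.node: s for s in states}

        stage = "paleo"
        curve = None
        if "paleo" in config.stages:
            if config.d18o_csv:
                series = paleo.IsotopeSeries.from_csv(config.d18o_csv)
            else:
                series = sim_delta18o(seed=config.seed)
            smoothed = paleo.running_mean(series, config.window)
            curve = paleo.calibrate(smoothed,
                                    paleo.CalibrationAnchors(tuple(config.anchors)),
                                    window=config.window)
            p = out / "curve.csv"
            curve.to_frame().to_csv(p, index=False)
            artifacts["curve"] = p

        stage = "gateway"
        if "gateway" in config.stages:
            events = []
            for cladename, node in node_ids.items():
                age = float(ages_tbl.loc[node, "age_mean"])
                a = anc[node]
                route = "unknown"
                if recon is not None:
                    below = set(dated.node_tips()[node])
                    _, cross = dec.count_crossings(recon, dec.OLD_WORLD,
                                                   dec.NEW_WORLD)
                    for ev in cross:
                        if ev.branch in _subtree_nodes(dated, node):
                            route = ev.route
                            break
                events.append(gateway.ColonizationEvent(
                    clade=cladename, node=node, age_ma=age,
                    t_cold=a.mean_cold, t_warm=a.mean_warm,
                    ci_cold=a.ci_cold, ci_warm=a.ci_warm, route=route,
                    provenance={"ages": "grid mean", "mcmc": config.mcmc_preset}))
            events.sort(key=lambda e: -e.age_ma)
            p = out / "events.csv"
            pd.DataFrame([{
                "clade": e.clade, "node": e.node, "age_ma": e.age_ma,
                "t_cold": e.t_cold, "t_warm": e.t_warm, "route": e.route,
            } for e in events]).to_csv(p, index=False)
            artifacts["events"] = p
            trend = gateway.tolerance_trend_test(events, character="cold")
            p = out / "trend.json"
            p.write_text(json.dumps({
                "statistic": None if np.isnan(trend.statistic) else trend.statistic,
                "p_value": trend.p_value, "method": trend.method,
                "character": trend.character, "n": trend.n}, indent=1))
            artifacts["trend"] = p
            reports = gateway.beringia_match(events, curve)
            p = out / "match.csv"
            pd.DataFrame([r.__dict__ for r in reports]).to_csv(p, index=False)
            artifacts["match"] = p
            p = out / "gateway.png"
            gateway.plot_gateway(events, curve, str(p))
            artifacts["plot"] = p
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest["outputs"] = {k: {"path": str(v), "sha256": _sha256(v)}
                           for k, v in artifacts.items() if v.suffix != ".png"}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _subtree_nodes(tree: Phylogeny, node: int) -> set:
    out = set()
    stack = [node]
    while stack:
        n = stack.pop()
        out.add(n)
        stack.extend(tree.children[n])
    return out


def _chronogram_from_ages(tree: Phylogeny, ages: np.ndarray) -> Phylogeny:
    lengths = np.zeros(tree.n_nodes)
    for node in range(tree.n_nodes - 1):
        lengths[node] = max(ages[tree.parent[node]] - ages[node], 0.0)
    return Phylogeny(tree.parent, tree.children, lengths, tree.labels, "Ma",
                     dict(tree.annotations))
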