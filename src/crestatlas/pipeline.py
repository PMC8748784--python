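"""End-to-end orchestration: simulate -> QC -> score -> competency ->
constellation -> priming -> temporal graph, with a YAML config, a named
parameter preset, and a JSON run manifest recording seeds, parameters and
output checksums."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .competency import CompetencyConfig, competency_report
from .constellation import build_distance, embed, group_nodes
from .containers import ValidationError
from .io import qc_filter_cells
from .priming import find_priming_pairs
from .scoring import score_all
from .simulate import LineageSpec, simulate_atlas, write_truth
from .stitch import build_temporal_graph, write_graph

log = logging.getLogger("crestatlas")

#: Parameterization used by the zebrafish cranial-neural-crest study this
#: pipeline reimplements: QC FRIP > 0.5 with fragments in 1000..20000
#: (the default-stage thresholds), 50 matched backgrounds, skew cutoffs
#: 1 / 0.4 with max-score filter 15 at the earliest stage, constellation
#: weight a = 12, priming alpha 0.05, LSI rank 30 using components 2..30,
#: and k = 20 within-stage neighbors.
PRESETS: dict[str, dict] = {
    "zebrafish-cncc": {
        "qc": {"frip_min": 0.5, "frag_min": 1000, "frag_max": 20000},
        "scoring": {"n_background": 50},
        "competency": {
            "skew_cutoff": 1.0,
            "earliest_skew_cutoff": 0.4,
            "earliest_max_score": 15.0,
        },
        "constellation": {"a": 12.0, "n_neighbors": 15, "min_dist": 0.1},
        "priming": {"alpha": 0.05},
        "stitch": {"rank": 30, "component_lo": 2, "component_hi": 30,
                   "k_intra": 20, "k_link": 10},
    }
}

_KNOWN_SECTIONS = {
    "simulate", "qc", "scoring", "competency", "constellation", "priming",
    "stitch", "stages", "seed", "outdir", "preset",
}
_KNOWN_KEYS = {
    "simulate": {
        "n_tissues", "n_timepoints", "cells_per_timepoint",
        "peaks_per_tissue", "background_peaks", "effect_size",
        "family_effect", "family_size", "n_priming_pairs", "n_decoy_motifs",
        "depth_mu", "depth_sigma", "seed",
    },
    "qc": {"frip_min", "frag_min", "frag_max"},
    "scoring": {"n_background"},
    "competency": {"skew_cutoff", "earliest_skew_cutoff", "earliest_max_score"},
    "constellation": {"a", "n_neighbors", "min_dist", "n_groups"},
    "priming": {"alpha"},
    "stitch": {"rank", "component_lo", "component_hi", "k_intra", "k_link"},
}


@dataclass
class RunConfig:
    """Validated run configuration (see :data:`PRESETS` for the shipped
    study parameterization)."""

    seed: int = 0
    outdir: str = "atlas_run"
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate", "qc", "score", "competency", "constellation",
            "priming", "stitch",
        ]
    )
    simulate: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    scoring: dict = field(default_factory=dict)
    competency: dict = field(default_factory=dict)
    constellation: dict = field(default_factory=dict)
    priming: dict = field(default_factory=dict)
    stitch: dict = field(default_factory=dict)

    @classmethod
    def from_preset(cls, name: str = "zebrafish-cncc", **overrides) -> "RunConfig":
        if name not in PRESETS:
            raise ValidationError(f"unknown preset {name!r}")
        cfg = cls(**overrides)
        p = PRESETS[name]
        for section, values in p.items():
            getattr(cfg, section).update(values)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        report = validate_config(raw)
        if report["errors"]:
            raise ValidationError(
                "invalid config: " + "; ".join(report["errors"])
            )
        preset = raw.pop("preset", None)
        cfg = cls.from_preset(preset) if preset else cls()
        for key in ("seed", "outdir", "stages"):
            if key in raw:
                setattr(cfg, key, raw.pop(key))
        for section, values in raw.items():
            getattr(cfg, section).update(values or {})
        return cfg


def validate_config(raw: dict) -> dict:
    """Range-check every parameter; reject unknown keys. Returns a report
    (never raises)."""
    errors: list[str] = []
    for section in raw:
        if section not in _KNOWN_SECTIONS:
            errors.append(f"unknown config section {section!r}")
    for section, keys in _KNOWN_KEYS.items():
        for key in raw.get(section) or {}:
            if key not in keys:
                errors.append(f"unknown key {section}.{key}")
    def num(section, key, default=None):
        val = (raw.get(section) or {}).get(key, default)
        return val

    a = num("constellation", "a")
    if a is not None and a < 0:
        errors.append("constellation.a must be >= 0")
    alpha = num("priming", "alpha")
    if alpha is not None and not 0 < alpha <= 1:
        errors.append("priming.alpha must be in (0, 1]")
    eff = num("simulate", "effect_size")
    if eff is not None and eff < 1:
        errors.append("simulate.effect_size must be >= 1")
    nb = num("scoring", "n_background")
    if nb is not None and nb < 2:
        errors.append("scoring.n_background must be >= 2")
    frip = num("qc", "frip_min")
    if frip is not None and not 0 <= frip < 1:
        errors.append("qc.frip_min must be in [0, 1)")
    lo, hi = num("qc", "frag_min"), num("qc", "frag_max")
    if lo is not None and hi is not None and lo >= hi:
        errors.append("qc.frag_min must be < qc.frag_max")
    rank = num("stitch", "rank")
    if rank is not None and rank < 2:
        errors.append("stitch.rank must be >= 2")
    return {"valid": not errors, "errors": errors}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the run manifest (also written to ``manifest.json``); any
    stage failure aborts with the stage name attached.
    """
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: getattr(config, k)
            for k in (
                "simulate", "qc", "scoring", "competency", "constellation",
                "priming", "stitch",
            )
        },
        "stages": {},
        "outputs": {},
    }
    state: dict = {}

    def run_stage(name, fn):
        if name not in config.stages:
            return
        t0 = time.perf_counter()
        log.info("stage %s: start (seed=%d)", name, config.seed)
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "seed": config.seed,
        }
        log.info("stage %s: done in %.2fs", name,
                 manifest["stages"][name]["seconds"])

    def st_simulate():
        sim = dict(config.simulate)
        kwargs = {}
        if "n_tissues" in sim:
            kwargs["tissues"] = [
                f"tissue{i:02d}" for i in range(sim.pop("n_tissues"))
            ]
        if "n_timepoints" in sim:
            kwargs["timepoints"] = [
                f"T{i}" for i in range(sim.pop("n_timepoints"))
            ]
        mu = sim.pop("depth_mu", None)
        sigma = sim.pop("depth_sigma", None)
        if mu is not None or sigma is not None:
            kwargs["depth_lognormal"] = (mu or 9.0, sigma or 0.45)
        sim.setdefault("seed", config.seed)
        spec = LineageSpec(**kwargs, **sim)
        state["atlas"] = simulate_atlas(spec)
        state["spec"] = spec
        write_truth(state["atlas"].truth, outdir / "truth.tsv")

    def st_qc():
        atlas = state["atlas"]
        p = {"frip_min": 0.5, "frag_min": 1000, "frag_max": 20000,
             **config.qc}
        kept, reports = [], []
        keep_masks = []
        for m in atlas.matrices:
            filt, rep = qc_filter_cells(
                m, p["frip_min"], (p["frag_min"], p["frag_max"])
            )
            kept.append(filt)
            reports.append(asdict(rep))
            keep_masks.append(
                m.cells.index.isin(filt.cells.index)
            )
        state["matrices"] = kept
        # keep priming features aligned with retained cells
        state["motifs"] = [
            f.loc[m.barcodes]
            for f, m in zip(atlas.motif_deviations, kept)
        ]
        state["tfs"] = [
            f.loc[m.barcodes] for f, m in zip(atlas.tf_activity, kept)
        ]
        manifest["stages"].setdefault("qc_reports", reports)

    def st_score():
        atlas = state["atlas"]
        mats = state.get("matrices", atlas.matrices)
        nb = config.scoring.get("n_background", 50)
        scored = score_all(
            mats, atlas.modules, n_background=nb, seed=config.seed
        )
        state["scores"] = {s.timepoint: s.scores for s in scored}
        for s in scored:
            s.scores.to_csv(
                outdir / f"module_scores_{s.timepoint}.tsv", sep="\t"
            )

    def st_competency():
        cfg = CompetencyConfig(**{
            k: v for k, v in config.competency.items()
        })
        tps = [m.timepoint for m in state["matrices"]]
        report = competency_report(state["scores"], cfg, tps)
        state["competency"] = report
        report.table.to_csv(outdir / "competency.tsv", sep="\t", index=False)
        report.establishment_table().to_csv(
            outdir / "establishment.tsv", sep="\t"
        )

    def st_constellation():
        p = {"a": 12.0, "n_neighbors": 15, "min_dist": 0.1,
             **config.constellation}
        dist = build_distance(state["scores"], a=p["a"])
        coords = embed(
            dist, seed=config.seed, n_neighbors=p["n_neighbors"],
            min_dist=p["min_dist"],
        )
        n_groups = p.get("n_groups") or len(
            state["spec"].families()
        )
        groups = group_nodes(dist, k=min(n_groups, len(dist.nodes)))
        cmap = coords.copy()
        cmap["group"] = groups
        status = state.get("competency")
        if status is not None:
            lut = {
                (r.tissue, r.timepoint): r.status
                for r in status.table.itertuples()
            }
            cmap["status"] = [lut.get(n, "") for n in dist.nodes]
        state["constellation"] = (dist, cmap)
        cmap.to_csv(outdir / "constellation_map.tsv", sep="\t")
        dist.frame().to_csv(outdir / "constellation_distance.tsv", sep="\t")

    def st_priming():
        atlas = state["atlas"]
        alpha = config.priming.get("alpha", 0.05)
        est = state["competency"].establishment_table()
        tps = [m.timepoint for m in state["matrices"]]
        tp_index = {tp: i for i, tp in enumerate(tps)}
        all_pairs = []
        for tp in tps:
            tissues = [
                t for t, row in est.iterrows()
                if row["establishment"] == tp
            ]
            if not tissues:
                continue
            i = tp_index[tp]
            pairs = find_priming_pairs(
                state["scores"][tp][tissues],
                state["motifs"][i],
                state["tfs"][i],
                atlas.pairing_table,
                alpha=alpha,
            )
            pairs["timepoint"] = tp
            all_pairs.append(pairs)
        result = (
            pd.concat(all_pairs, ignore_index=True)
            if all_pairs
            else pd.DataFrame()
        )
        state["priming"] = result
        result.to_csv(outdir / "priming_pairs.tsv", sep="\t", index=False)

    def st_stitch():
        p = {"rank": 30, "component_lo": 2, "component_hi": 30,
             "k_intra": 20, "k_link": 10, **config.stitch}
        G = build_temporal_graph(
            state["matrices"],
            k_intra=p["k_intra"],
            k_link=p["k_link"],
            rank=p["rank"],
            component_range=(p["component_lo"], p["component_hi"]),
        )
        state["graph"] = G
        write_graph(G, outdir)

    run_stage("simulate", st_simulate)
    run_stage("qc", st_qc)
    run_stage("score", st_score)
    run_stage("competency", st_competency)
    run_stage("constellation", st_constellation)
    run_stage("priming", st_priming)
    run_stage("stitch", st_stitch)

    for path in sorted(outdir.glob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][path.name] = _sha256(path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    state["manifest"] = manifest
    return state
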