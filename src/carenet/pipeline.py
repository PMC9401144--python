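"""End-to-end orchestration: simulate -> episodes -> network -> embed ->
fit -> communities, from one YAML config, with a JSON manifest of outputs.

Every stage consumes the previous stage's files, all randomness derives from
the global seed, and numeric CSV output uses fixed 12-significant-digit
formatting so reruns are hash-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import community as community_mod
from . import embedding as embedding_mod
from . import episodes as episodes_mod
from . import network as network_mod
from . import regression as regression_mod
from . import synth as synth_mod

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_all", "StageError"]

FLOAT_FMT = "%.12g"


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated, fully-defaulted configuration for a pipeline run."""

    synth: synth_mod.SynthConfig = field(default_factory=synth_mod.SynthConfig)
    tau1: float = 10.0
    tau2: float = 35.0
    max_days: float = 400.0
    node2vec: dict = field(default_factory=lambda: {
        "t": 7, "l": 60, "w": 13, "d": 75, "p": 16.0, "q": 1.0 / 32.0,
        "epochs": 5, "learning_rate": 0.5,
    })
    folds: int = 5
    n_embedding_draws: int = 5
    seed: int = 0
    out_dir: str = "carenet_out"
    verbosity: str = "info"


_TOP_KEYS = {"synth", "tau1", "tau2", "max_days", "node2vec", "folds",
             "n_embedding_draws", "seed", "out_dir", "verbosity"}


def validate_config(path_or_dict) -> RunConfig:
    """Load a YAML config, fill defaults, reject unknown keys, type-check."""
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        raw = dict(path_or_dict or {})
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig()
    if "synth" in raw:
        synth_fields = {f.name for f in dataclasses.fields(synth_mod.SynthConfig)}
        bad = set(raw["synth"]) - synth_fields
        if bad:
            raise ValueError(f"unknown keys under synth: {sorted(bad)}")
        try:
            cfg.synth = synth_mod.SynthConfig(**raw["synth"])
        except TypeError as exc:
            raise ValueError(f"synth: {exc}") from exc
        cfg.synth.validate()
    for key in ("tau1", "tau2", "max_days"):
        if key in raw:
            v = raw[key]
            if not isinstance(v, (int, float)) or v < 0:
                raise ValueError(f"{key}: must be a non-negative number, got {v!r}")
            setattr(cfg, key, float(v))
    if "node2vec" in raw:
        bad = set(raw["node2vec"]) - set(cfg.node2vec)
        if bad:
            raise ValueError(f"unknown keys under node2vec: {sorted(bad)}")
        cfg.node2vec.update(raw["node2vec"])
        for k in ("t", "l", "w", "d", "epochs"):
            if not isinstance(cfg.node2vec[k], int) or cfg.node2vec[k] < 1:
                raise ValueError(f"node2vec.{k}: must be a positive integer")
        for k in ("p", "q", "learning_rate"):
            if not isinstance(cfg.node2vec[k], (int, float)) or cfg.node2vec[k] <= 0:
                raise ValueError(f"node2vec.{k}: must be positive")
    for key in ("folds", "n_embedding_draws", "seed"):
        if key in raw:
            if not isinstance(raw[key], int):
                raise ValueError(f"{key}: must be an integer, got {raw[key]!r}")
            setattr(cfg, key, raw[key])
    if cfg.folds < 2:
        raise ValueError("folds: must be >= 2")
    for key in ("out_dir", "verbosity"):
        if key in raw:
            setattr(cfg, key, str(raw[key]))
    return cfg


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    timings: dict[str, float] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                fn()
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc
            timings[name] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s: done in %.2fs", name, timings[name])
        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        cfg = dataclasses.replace(config.synth, seed=config.seed)
        providers, patients, claims, truth = synth_mod.simulate(cfg)
        synth_mod.write_claims(claims, out / "claims.csv")
        _write_csv(providers, out / "providers.csv")
        truth_payload = {
            "provider_coop": truth.provider_coop,
            "provider_area": truth.provider_area,
            "provider_community": truth.provider_community,
            "community_offset": truth.community_offset,
        }
        (out / "ground_truth.json").write_text(json.dumps(truth_payload, sort_keys=True))
        artifacts.extend([out / "claims.csv", out / "providers.csv",
                          out / "ground_truth.json"])
        state.update(providers=providers, claims=claims)

    @stage("episodes")
    def _episodes():
        claims = synth_mod.read_claims(out / "claims.csv")
        eps = episodes_mod.link_records(
            claims, episodes_mod.LinkageParams(tau1=config.tau1, tau2=config.tau2)
        )
        state["episodes"] = eps
        rows = [{
            "episode_id": f"e{i:06d}", "patient_id": e.patient_id,
            "D_in": e.D_in, "H": ";".join(sorted(e.H)),
            "has_surgery": e.has_surgery, "age": e.age_at_admission,
            "sex": e.sex, "n_hospital_providers": e.n_hospital_providers,
        } for i, e in enumerate(eps)]
        _write_csv(pd.DataFrame(rows), out / "episodes.csv")
        artifacts.append(out / "episodes.csv")

    @stage("network")
    def _network():
        claims = state["claims"]
        bip = network_mod.build_bipartite(claims)
        G = network_mod.project_cosine(bip, state["providers"])
        gc = network_mod.giant_component(G)
        state["graph"] = gc
        state["strengths"] = network_mod.strengths(gc)
        edges = pd.DataFrame(
            [(u, v, d["weight"]) for u, v, d in sorted(gc.edges(data=True))],
            columns=["src", "dst", "weight"],
        )
        _write_csv(edges, out / "network_edges.csv")
        feats = network_mod.network_features(gc)
        scalar = {k: v for k, v in feats.items() if not isinstance(v, dict)}
        (out / "network_features.json").write_text(
            json.dumps(scalar, sort_keys=True, default=float))
        artifacts.extend([out / "network_edges.csv", out / "network_features.json"])

    @stage("cases")
    def _cases():
        eps = state["episodes"]
        cases = episodes_mod.filter_cases(eps, set(state["graph"].nodes),
                                          max_days=config.max_days)
        state["cases"] = cases
        _write_csv(cases, out / "cases.csv")
        artifacts.append(out / "cases.csv")

    @stage("fit")
    def _fit():
        nv = config.node2vec
        table = regression_mod.compare_models(
            state["cases"], state["strengths"], state["graph"],
            seed=config.seed, folds=config.folds,
            n_embedding_draws=config.n_embedding_draws,
            walk=embedding_mod.WalkParams(t=nv["t"], l=nv["l"], p=nv["p"], q=nv["q"]),
            d=nv["d"], w=nv["w"], epochs=nv["epochs"],
        )
        state["comparison"] = table
        _write_csv(table, out / "model_comparison.csv")
        artifacts.append(out / "model_comparison.csv")

    @stage("communities")
    def _communities():
        part = community_mod.detect_communities(state["graph"], seed=config.seed)
        feats = community_mod.community_features(
            state["graph"], part, state["providers"], state["strengths"])
        part_df = pd.DataFrame(sorted(part.assignment.items()),
                               columns=["node", "community"])
        _write_csv(part_df, out / "communities.csv")
        _write_csv(feats, out / "community_features.csv")
        artifacts.extend([out / "communities.csv", out / "community_features.csv"])
        state["partition"] = part

    manifest = {
        "seed": config.seed,
        "stages": timings,
        "files": [
            {"path": p.name, "sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in artifacts
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
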