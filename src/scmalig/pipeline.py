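"""End-to-end pipeline with config, manifest and determinism guarantees.

Stages run in a fixed order (simulate -> qc -> normalize -> cnv ->
classify -> score -> subtype -> markers) and communicate through
on-disk standard formats (MTX / TSV / JSON), so each stage is
independently inspectable and a manifest of parameter and output hashes
suffices to reproduce any stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnv as cnv_mod
from . import io as io_mod
from . import malignancy as mal_mod
from . import markers as mk_mod
from . import preprocess as pp_mod
from . import scoring as sc_mod
from . import subtyping as st_mod
from . import synthetic as syn_mod
from .io import GeneSet

log = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "normalize", "cnv", "classify", "score", "subtype",
          "markers"]

# stage -> stages it needs upstream
_REQUIRES = {
    "qc": ["simulate_or_input"],
    "normalize": ["qc"],
    "cnv": ["normalize"],
    "classify": ["cnv"],
    "score": ["normalize"],
    "subtype": ["score", "classify"],
    "markers": ["normalize"],
}


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A stage failed during execution."""


def _take(section: dict, allowed: dict, name: str) -> dict:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    out = dict(allowed)
    out.update(section)
    return out


@dataclass
class PipelineConfig:
    """Schema-validated pipeline configuration; unknown keys rejected."""

    seed: int = 7
    input_dir: str | None = None
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    simulate: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    normalize: dict = field(default_factory=dict)
    cnv: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    score: dict = field(default_factory=dict)
    subtype: dict = field(default_factory=dict)
    markers: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        top = {"seed", "input_dir", "stages"} | set(STAGES)
        unknown = set(raw) - top
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        cfg = cls(
            seed=int(raw.get("seed", 7)),
            input_dir=raw.get("input_dir"),
            stages={s: True for s in STAGES},
        )
        stages = raw.get("stages", {})
        bad = set(stages) - set(STAGES)
        if bad:
            raise ConfigError(f"unknown stage(s): {sorted(bad)}")
        cfg.stages.update({k: bool(v) for k, v in stages.items()})
        cfg.simulate = _take(raw.get("simulate", {}),
                             {"kind": "default"}, "simulate")
        cfg.qc = _take(raw.get("qc", {}),
                       {"min_genes": 200, "max_genes": 6000, "max_mito": 0.10},
                       "qc")
        cfg.normalize = _take(raw.get("normalize", {}),
                              {"scale_factor": 10000.0}, "normalize")
        cfg.cnv = _take(
            raw.get("cnv", {}),
            {"window": 101, "clip": 3.0, "reference_group": "NT",
             "score_method": "mean_square", "include_mito": False},
            "cnv",
        )
        cfg.classify = _take(
            raw.get("classify", {}),
            {"top_fraction": 0.05, "score_thresh": 0.001, "r_thresh": 0.5,
             "correlate_on": "cnv"},
            "classify",
        )
        cfg.score = _take(
            raw.get("score", {}),
            {"n_bins": 24, "n_ctrl": 100, "gmt": None, "standin_size": 30},
            "score",
        )
        cfg.subtype = _take(raw.get("subtype", {}), {"level": "sample"}, "subtype")
        cfg.markers = _take(
            raw.get("markers", {}),
            {"logfc_thresh": 0.25, "min_pct": 0.25, "only_pos": True,
             "alpha": 0.05},
            "markers",
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        if not self.stages.get("simulate") and not self.input_dir:
            if any(self.stages.get(s) for s in STAGES[1:]):
                raise ConfigError(
                    "simulate disabled and no input_dir: nothing to process"
                )
        for stage, reqs in _REQUIRES.items():
            if not self.stages.get(stage):
                continue
            for req in reqs:
                if req == "simulate_or_input":
                    if not (self.stages.get("simulate") or self.input_dir):
                        raise ConfigError("qc needs a simulated cohort or input_dir")
                elif not self.stages.get(req):
                    raise ConfigError(
                        f"stage '{stage}' requires stage '{req}' to be enabled"
                    )
        if self.subtype["level"] not in ("sample", "cluster"):
            raise ConfigError("subtype.level must be 'sample' or 'cluster'")
        if self.simulate["kind"] not in ("default", "two_clone"):
            raise ConfigError("simulate.kind must be 'default' or 'two_clone'")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(params: dict) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the enabled stages in order; return the run manifest.

    Identical config + seed reproduce byte-identical outputs.  A stage
    failure raises :class:`StageError` after writing a manifest that
    marks the failed stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.validate()
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "stages": [],
    }
    state: dict = {}

    def record(stage: str, params: dict, outputs: list[Path]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "enabled": True,
                "params_hash": _params_hash(params),
                "params": params,
                "outputs": {
                    str(p.relative_to(outdir)): _sha256(p) for p in outputs
                },
            }
        )

    try:
        for stage in STAGES:
            if not config.stages.get(stage):
                manifest["stages"].append({"stage": stage, "enabled": False})
                continue
            outputs = _run_stage(stage, config, outdir, state)
            record(stage, getattr(config, stage), outputs)
    except Exception as e:
        manifest["failed_stage"] = stage
        manifest["error"] = str(e)
        _write_manifest(manifest, outdir)
        raise StageError(f"stage '{stage}' failed: {e}") from e
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _load_cohort(config: PipelineConfig, outdir: Path):
    src = outdir / "cohort" if config.stages.get("simulate") else Path(config.input_dir)
    return io_mod.read_cohort(src)


def _run_stage(stage: str, config: PipelineConfig, outdir: Path, state: dict):
    log.info("running stage %s", stage)
    if stage == "simulate":
        factory = (
            syn_mod.default_config
            if config.simulate["kind"] == "default"
            else syn_mod.two_clone_config
        )
        counts, ann, cells, truth = syn_mod.generate_cohort(factory(config.seed))
        io_mod.write_cohort(outdir / "cohort", counts, ann, cells, truth)
        state["truth"] = truth
        return sorted((outdir / "cohort").glob("*"))

    if stage == "qc":
        counts, ann, cells = _load_cohort(config, outdir)
        filtered, report = pp_mod.qc_filter(
            counts, ann,
            min_genes=config.qc["min_genes"],
            max_genes=config.qc["max_genes"],
            max_mito=config.qc["max_mito"],
        )
        fdir = outdir / "filtered"
        io_mod.write_cohort(fdir, filtered, ann, cells)
        _write_tsv(report, outdir / "qc_report.tsv")
        state.update(counts=filtered, annotation=ann,
                     cells=cells.reindex(filtered.cell_ids))
        return sorted(fdir.glob("*")) + [outdir / "qc_report.tsv"]

    if stage == "normalize":
        norm = pp_mod.normalize(state["counts"], config.normalize["scale_factor"])
        from scipy import io as spio

        spio.mmwrite(str(outdir / "normalized.mtx"), norm.X.tocoo())
        state["norm"] = norm
        return [outdir / "normalized.mtx"]

    if stage == "cnv":
        cells = state["cells"]
        ref_group = config.cnv["reference_group"]
        ref_cells = cells.index[cells["group"] == ref_group].tolist()
        profile = cnv_mod.infer_cnv(
            state["norm"], state["annotation"], ref_cells,
            window=config.cnv["window"], clip=config.cnv["clip"],
            include_mito=config.cnv["include_mito"],
        )
        scores = cnv_mod.cnv_score(profile, method=config.cnv["score_method"])
        io_mod.write_matrix_mtx(outdir / "cnv_profile.mtx", profile.values)
        _write_tsv(scores.to_frame(), outdir / "cnv_scores.tsv")
        state.update(profile=profile, cnv_scores=scores)
        return [outdir / "cnv_profile.mtx", outdir / "cnv_scores.tsv"]

    if stage == "classify":
        cells = state["cells"]
        calls = mal_mod.call_malignancy(
            state["profile"], state["cnv_scores"], cells["group"],
            top_fraction=config.classify["top_fraction"],
            score_thresh=config.classify["score_thresh"],
            r_thresh=config.classify["r_thresh"],
            reference_groups=(config.cnv["reference_group"],),
            correlate_on=config.classify["correlate_on"],
            norm=state["norm"],
        )
        calls["group"] = cells["group"].reindex(calls.index)
        _write_tsv(calls, outdir / "malignancy_calls.tsv")
        state["calls"] = calls
        return [outdir / "malignancy_calls.tsv"]

    if stage == "score":
        norm = state["norm"]
        sets = [GeneSet("NE", list(syn_mod.NE_SIGNATURE))]
        if config.score["gmt"]:
            sets += io_mod.read_gmt(config.score["gmt"])
        else:
            sets += _standin_sets(norm, config.seed, config.score["standin_size"])
        table = sc_mod.score_modules(
            norm, sets,
            n_bins=config.score["n_bins"], n_ctrl=config.score["n_ctrl"],
            seed=config.seed,
        )
        table["cnv"] = state["cnv_scores"].reindex(table.index)
        _write_tsv(table, outdir / "module_scores.tsv")
        state["module_scores"] = table
        return [outdir / "module_scores.tsv"]

    if stage == "subtype":
        cells = state["cells"]
        calls = state["calls"]
        malignant = calls.index[calls["label"] == mal_mod.MALIGNANT]
        scores = state["module_scores"]
        outputs = []
        needed = {"emt", "proliferation", "antigen_presentation"}
        if needed <= set(scores.columns) and len(malignant) > 0:
            msc = scores.loc[malignant]
            summary = st_mod.summarize_clusters(
                msc, cells.loc[malignant, "cluster"]
            )
            _write_tsv(summary, outdir / "cluster_scores.tsv")
            outputs.append(outdir / "cluster_scores.tsv")
            if len(summary) >= 3:
                states = st_mod.assign_states(summary)
                _write_tsv(states, outdir / "states.tsv")
                outputs.append(outdir / "states.tsv")
            else:
                log.warning("fewer than 3 malignant clusters; states skipped")
        unit_col = "sample_id" if config.subtype["level"] == "sample" else "cluster"
        units = cells.loc[malignant, unit_col] if len(malignant) else None
        if units is not None and len(units) > 0:
            sub = st_mod.call_subtype(
                state["norm"].subset_cells(np.asarray(malignant)), units
            )
            _write_tsv(sub, outdir / "subtypes.tsv")
            outputs.append(outdir / "subtypes.tsv")
        else:
            log.warning("no malignant cells; subtype calls skipped")
        return outputs

    if stage == "markers":
        cells = state["cells"]
        table = mk_mod.rank_markers(
            state["norm"], cells["cluster"],
            logfc_thresh=config.markers["logfc_thresh"],
            min_pct=config.markers["min_pct"],
            only_pos=config.markers["only_pos"],
            alpha=config.markers["alpha"],
        )
        _write_tsv(table, outdir / "markers.tsv", index=False)
        return [outdir / "markers.tsv"]

    raise StageError(f"unknown stage {stage!r}")  # pragma: no cover


def _standin_sets(norm, seed: int, size: int) -> list[GeneSet]:
    """Synthetic stand-in program sets (EMT / proliferation / antigen
    presentation) drawn deterministically from the matrix genes; real
    analyses should supply curated sets via a GMT file."""
    rng = np.random.default_rng([seed, 0xC0FFEE])
    genes = np.asarray(norm.gene_ids)
    sets = []
    for name in ["emt", "proliferation", "antigen_presentation"]:
        pick = rng.choice(genes.size, size=min(size, genes.size), replace=False)
        sets.append(GeneSet(name, genes[np.sort(pick)].tolist()))
    return sets
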