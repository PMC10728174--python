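"""End-to-end orchestration: transloc-filter -> call -> analyze.

A run is described by a YAML config naming the primer pool, an output
directory, per-sample inputs (FASTQ pairs and/or pileup files), and the
analysis parameters.  Samples come in matched ±DSB pairs per treatment
(damaged = plus_dsb, undamaged = minus_dsb); the damaged-undamaged delta
is computed per treatment, and treatments other than the control are
additionally reported as the chained delta against the control treatment.

The alignment/pileup stage wraps external tools (read filter, aligner,
pileup generator) behind a documented subprocess contract and is disabled
by default; pileup inputs bypass it entirely, which is also how the test
suite exercises the pipeline.  Translocated reads are filtered out before
alignment, so the transloc stage is a mandatory predecessor of calling
when starting from FASTQ.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .amplicon_catalog import PrimerPool, load_primer_pool
from .errors import FormatError
from .mutation_analysis import (
    chained_treatment_delta,
    delta_profiles,
    locus_summary,
    metagene_profile,
    translocation_summary,
)
from .mutation_caller import annotations_to_frame, pileup_to_profile
from .translocapture import scan_fastq

logger = logging.getLogger("imutseq.pipeline")

_PARAM_DEFAULTS = {
    "min_depth": 100,
    "adjacency_bp": 10,
    "window": 100,
    "max_mismatch": 1,
    "seed": 0,
}
_STAGE_DEFAULTS = {"transloc": True, "call": True, "analyze": True, "align": False}
_SAMPLE_KEYS = {"id", "condition", "treatment", "r1", "r2", "pileup"}
_TOP_KEYS = {"pool", "out_dir", "samples", "params", "stages", "control_treatment"}


@dataclass
class Sample:
    id: str
    condition: str  # "plus_dsb" | "minus_dsb"
    treatment: str
    r1: Optional[str] = None
    r2: Optional[str] = None
    pileup: Optional[str] = None


@dataclass
class RunConfig:
    pool: str
    out_dir: str
    samples: list
    params: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    control_treatment: str = "CTRLsi"

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.id == sample_id:
                return s
        raise KeyError(sample_id)

    def treatments(self) -> list:
        seen = []
        for s in self.samples:
            if s.treatment not in seen:
                seen.append(s.treatment)
        return seen

    def pair(self, treatment: str) -> tuple:
        plus = [s for s in self.samples if s.treatment == treatment and s.condition == "plus_dsb"]
        minus = [s for s in self.samples if s.treatment == treatment and s.condition == "minus_dsb"]
        if len(plus) != 1 or len(minus) != 1:
            raise FormatError(
                f"treatment {treatment!r} needs exactly one plus_dsb and one minus_dsb sample"
            )
        return plus[0], minus[0]

    def to_dict(self) -> dict:
        return {
            "pool": self.pool,
            "out_dir": self.out_dir,
            "control_treatment": self.control_treatment,
            "params": dict(self.params),
            "stages": dict(self.stages),
            "samples": [
                {k: v for k, v in vars(s).items() if v is not None} for s in self.samples
            ],
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Load, validate and default-fill a YAML run config.

    Unknown keys raise (no silent ignore); every plus_dsb sample must have
    a matched minus_dsb sample within its treatment, and enabled stages
    must have the inputs they need.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise FormatError(f"{path}: unknown config key(s) {sorted(unknown)}")
    for key in ("pool", "out_dir", "samples"):
        if key not in raw:
            raise FormatError(f"{path}: missing required key {key!r}")
    params = dict(_PARAM_DEFAULTS)
    bad = set(raw.get("params", {})) - set(_PARAM_DEFAULTS)
    if bad:
        raise FormatError(f"{path}: unknown params key(s) {sorted(bad)}")
    params.update(raw.get("params", {}))
    stages = dict(_STAGE_DEFAULTS)
    bad = set(raw.get("stages", {})) - set(_STAGE_DEFAULTS)
    if bad:
        raise FormatError(f"{path}: unknown stages key(s) {sorted(bad)}")
    stages.update(raw.get("stages", {}))

    samples = []
    for i, s in enumerate(raw["samples"]):
        unknown = set(s) - _SAMPLE_KEYS
        if unknown:
            raise FormatError(f"{path}: sample {i}: unknown key(s) {sorted(unknown)}")
        for key in ("id", "condition", "treatment"):
            if key not in s:
                raise FormatError(f"{path}: sample {i}: missing {key!r}")
        if s["condition"] not in ("plus_dsb", "minus_dsb"):
            raise FormatError(f"{path}: sample {i}: bad condition {s['condition']!r}")
        samples.append(Sample(**s))

    cfg = RunConfig(
        pool=str(Path(path).parent / raw["pool"]) if not Path(raw["pool"]).is_absolute() else raw["pool"],
        out_dir=raw["out_dir"],
        samples=samples,
        params=params,
        stages=stages,
        control_treatment=raw.get("control_treatment", "CTRLsi"),
    )
    # pairing invariant
    for treatment in cfg.treatments():
        cfg.pair(treatment)
    # inputs exist for enabled stages
    for s in samples:
        if stages["transloc"] and s.r1:
            for p in (s.r1, s.r2):
                if p is None or not Path(p).exists():
                    raise FormatError(f"sample {s.id}: FASTQ path {p!r} missing")
        if stages["call"] and s.pileup and not Path(s.pileup).exists():
            raise FormatError(f"sample {s.id}: pileup path {s.pileup!r} missing")
    return cfg


def write_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialize the effective (normalized, default-filled) config."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns a manifest of written outputs.

    Per sample: a translocation matrix and split FASTQs (transloc stage),
    an mprofile and deletion annotations (call stage).  Per treatment: the
    ±DSB delta, metagene profiles and per-locus summaries; non-control
    treatments additionally get the chained delta against the control.
    Every output directory carries a provenance file with the config hash
    and seed.  Any stage failure aborts with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pool = load_primer_pool(config.pool, max_mismatch=config.params["max_mismatch"])
    manifest: dict = {"outputs": [], "counts": {}, "config_hash": config.config_hash()}
    t0 = time.time()

    def _emit(path: Path) -> None:
        manifest["outputs"].append(str(path))

    stage = "transloc"
    try:
        profiles = {}
        annotations = {}
        for s in config.samples:
            if config.stages["transloc"] and s.r1 and s.r2:
                prefix = out_dir / s.id
                matrix, report = scan_fastq(
                    s.r1, s.r2, pool,
                    max_mismatch=config.params["max_mismatch"],
                    out_prefix=prefix,
                )
                matrix.to_csv(out_dir / f"{s.id}.transloc_counts.csv",
                              out_dir / f"{s.id}.transloc_rates.csv")
                _emit(out_dir / f"{s.id}.transloc_counts.csv")
                manifest["counts"][s.id] = report
                summary = translocation_summary(matrix, pool)
                summary["class_pairs"].to_csv(out_dir / f"{s.id}.transloc_classes.csv")
                _emit(out_dir / f"{s.id}.transloc_classes.csv")
                logger.info("transloc %s: %s", s.id, report)

        stage = "call"
        for s in config.samples:
            if config.stages["call"] and s.pileup:
                profile, anns = pileup_to_profile(
                    s.pileup, pool, adjacency_bp=config.params["adjacency_bp"]
                )
                profiles[s.id] = profile
                annotations[s.id] = anns
                profile.to_tsv(out_dir / f"{s.id}.mprofile.tsv", config.params["min_depth"])
                annotations_to_frame(anns).to_csv(
                    out_dir / f"{s.id}.deletions.tsv", sep="\t", index=False
                )
                _emit(out_dir / f"{s.id}.mprofile.tsv")
                _emit(out_dir / f"{s.id}.deletions.tsv")
                med = profile.counts["depth"].median() if len(profile.counts) else 0
                if med < 10 * config.params["min_depth"]:
                    logger.warning("call %s: median depth %s < 10x min_depth", s.id, med)

        stage = "analyze"
        deltas = {}
        if config.stages["analyze"]:
            md, w = config.params["min_depth"], config.params["window"]
            for treatment in config.treatments():
                plus, minus = config.pair(treatment)
                if plus.id not in profiles or minus.id not in profiles:
                    continue
                delta = delta_profiles(profiles[plus.id], profiles[minus.id], md)
                deltas[treatment] = delta
                delta.to_csv(out_dir / f"{treatment}.delta.tsv", sep="\t", float_format="%.6g")
                _emit(out_dir / f"{treatment}.delta.tsv")
                for group in ("HR", "NHEJ"):
                    if pool.by_class(group):
                        mg = metagene_profile(delta, pool, group, window=w)
                        mg.to_csv(out_dir / f"{treatment}.metagene.{group}.tsv", sep="\t",
                                  float_format="%.6g")
                        _emit(out_dir / f"{treatment}.metagene.{group}.tsv")
                summ = locus_summary(
                    profiles[plus.id], annotations.get(plus.id, []), pool,
                    window=w, min_depth=md, adjacency_bp=config.params["adjacency_bp"],
                )
                summ.to_csv(out_dir / f"{treatment}.locus_summary.tsv", sep="\t",
                            float_format="%.6g")
                _emit(out_dir / f"{treatment}.locus_summary.tsv")
            ctrl = config.control_treatment
            if ctrl in deltas:
                for treatment, delta in deltas.items():
                    if treatment == ctrl:
                        continue
                    chained = delta.copy()
                    for c in delta.columns:
                        if c in deltas[ctrl].columns and c not in (
                            "ref_base", "rel_pos", "depth_a", "depth_b"
                        ):
                            chained[c] = delta[c] - deltas[ctrl][c]
                    chained.to_csv(out_dir / f"{treatment}.chained_delta.tsv", sep="\t",
                                   float_format="%.6g")
                    _emit(out_dir / f"{treatment}.chained_delta.tsv")
    except Exception as exc:
        (out_dir / "INCOMPLETE").write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.params["seed"],
        "elapsed_s": round(time.time() - t0, 3),
        "counts": manifest["counts"],
    }
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    write_config(RunConfig(**{**vars(config)}), out_dir / "effective_config.yaml")
    manifest["provenance"] = provenance
    return manifest
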