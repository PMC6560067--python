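"""Pipeline orchestration: simulate -> trim -> align -> extract -> test.

Runs the full analysis from a single config (YAML/JSON or in-memory),
writing per-stage outputs, a JSON-lines run log with read-count
conservation checks, and the final dependence-call table.  Reruns with
the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import simulate as sim
from .align import AlignParams, align_reads, write_sam
from .diffmeth import call_dependent_sites
from .extract import (
    ArtifactFilterParams,
    call_read,
    filter_artifact_reads,
    pileup,
    write_site_outputs,
)
from .reference import ReferenceBundle
from .simulate import MethylationProfile, SimulationConfig, demo_reference
from .trim import TrimParams, trim_fastq

from Bio import SeqIO


@dataclass
class ProfileSite:
    transcript: str
    offset: int
    levels: dict[str, float]


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    conditions: list[str] = field(default_factory=lambda: ["ctr", "K190M", "NSUN2"])
    comparators: tuple[str, str] = ("ctr", "K190M")
    rescue: str = "NSUN2"
    reference_seed: int = 7
    flank_len: int = 50
    profile_sites: list[ProfileSite] = field(default_factory=list)
    background: float = 0.0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    trim: TrimParams = field(default_factory=TrimParams)
    align: AlignParams = field(default_factory=AlignParams)
    extract: ArtifactFilterParams = field(default_factory=ArtifactFilterParams)
    alpha: float = 0.05
    min_cov: int = 10
    external_fastqs: dict[str, str] = field(default_factory=dict)

    def build_profile(self) -> MethylationProfile:
        profile = MethylationProfile(background=self.background)
        for ps in self.profile_sites:
            for cond, m in ps.levels.items():
                profile.set(ps.transcript, ps.offset, cond, m)
        return profile


def default_demo_config(outdir, seed: int = 1, **overrides) -> PipelineConfig:
    """Bundled demo: one rescue-only m5C site (VTRNA1.1 C69 methylated at
    0.35 only when the wild-type enzyme is re-expressed)."""
    cfg = PipelineConfig(
        outdir=str(outdir),
        seed=seed,
        profile_sites=[
            ProfileSite("VTRNA1.1", 68, {"NSUN2": 0.35, "ctr": 0.0, "K190M": 0.0})
        ],
    )
    cfg.simulation = dataclasses.replace(cfg.simulation, seed=seed)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# Config file round-trip and validation


def config_to_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["comparators"] = list(cfg.comparators)
    return d


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    for key, cls in (
        ("simulation", SimulationConfig),
        ("trim", TrimParams),
        ("align", AlignParams),
        ("extract", ArtifactFilterParams),
    ):
        if key in d and isinstance(d[key], dict):
            d[key] = cls(**d[key])
    if "profile_sites" in d:
        d["profile_sites"] = [
            ProfileSite(**ps) if isinstance(ps, dict) else ps
            for ps in d["profile_sites"]
        ]
    if "comparators" in d:
        d["comparators"] = tuple(d["comparators"])
    return PipelineConfig(**d)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} is not a mapping")
    return config_from_dict(data)


def validate_config(path) -> dict:
    """Validate a config file; returns {'valid': bool, 'errors': [...]}.

    Field-constructor errors (out-of-range rates, bad replicate counts)
    and dangling file paths are reported by name.
    """
    errors: list[str] = []
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        return {"valid": False, "errors": [f"unreadable config: {exc}"]}
    if not isinstance(data, dict):
        return {"valid": False, "errors": ["config is not a mapping"]}
    if "outdir" not in data:
        errors.append("missing required field: outdir")
        data = {**data, "outdir": "."}
    for key, cls in (
        ("simulation", SimulationConfig),
        ("trim", TrimParams),
        ("align", AlignParams),
        ("extract", ArtifactFilterParams),
    ):
        block = data.get(key, {})
        if isinstance(block, dict):
            try:
                cls(**block)
            except (TypeError, ValueError) as exc:
                errors.append(f"{key}: {exc}")
    cfg = None
    if not errors:
        try:
            cfg = config_from_dict(data)
        except (TypeError, ValueError) as exc:
            errors.append(str(exc))
    if cfg is not None:
        for name, p in cfg.external_fastqs.items():
            if not Path(p).exists():
                errors.append(f"external fastq {name}: missing file {p}")
        if not (0 < cfg.alpha < 1):
            errors.append(f"alpha: {cfg.alpha} outside (0, 1)")
        missing = {*cfg.comparators, cfg.rescue} - set(cfg.conditions)
        if missing:
            errors.append(f"conditions missing comparator/rescue: {sorted(missing)}")
    return {"valid": not errors, "errors": errors}


# ---------------------------------------------------------------------------
# Pipeline


def _read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage


def run_pipeline(
    config: PipelineConfig, reference: ReferenceBundle | None = None
) -> dict:
    """Execute all stages; returns a result bundle of paths and tables.

    The run log (``run_log.jsonl``) records per-stage read counts; the
    conservation identities (input = kept + dropped; kept = unique +
    ambiguous + unaligned + discarded_short; unique = filter-kept +
    artifact-discarded) are asserted for every replicate.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run_log.jsonl"
    log_fh = open(log_path, "w")

    def log(stage: str, **fields):
        log_fh.write(json.dumps({"stage": stage, **fields}, sort_keys=True) + "\n")
        log_fh.flush()

    if reference is None:
        reference = demo_reference(config.reference_seed, config.flank_len)
    profile = config.build_profile()
    stage = "simulate"
    try:
        if config.external_fastqs:
            fastqs = {}
            for name, p in config.external_fastqs.items():
                cond, rep = name.rsplit(".rep", 1)
                fastqs[(cond, int(rep))] = p
        else:
            manifest = sim.simulate_study(
                reference, profile, config.simulation, config.conditions,
                outdir / "fastq",
            )
            fastqs = {
                (name.rsplit(".rep", 1)[0], int(name.rsplit(".rep", 1)[1])): p
                for name, p in manifest["fastqs"].items()
            }
        log("simulate", n_fastqs=len(fastqs), seed=config.seed)

        tables = []
        (outdir / "trimmed").mkdir(exist_ok=True)
        (outdir / "align").mkdir(exist_ok=True)
        (outdir / "meth").mkdir(exist_ok=True)
        for (cond, rep), fq in sorted(fastqs.items()):
            stage = "trim"
            trimmed_path, tstats = trim_fastq(
                fq, config.trim, outdir / "trimmed" / f"{cond}.rep{rep}.fastq"
            )
            assert tstats.n_in == tstats.n_kept + tstats.n_dropped
            log("trim", condition=cond, replicate=rep, n_in=tstats.n_in,
                n_kept=tstats.n_kept, n_dropped=tstats.n_dropped,
                n_trimmed=tstats.n_trimmed)

            stage = "align"
            reads = _read_fastq(trimmed_path)
            outcomes, astats = align_reads(reads, reference, config.align)
            tally: dict[str, int] = {}
            for o in outcomes:
                tally[o.outcome_class] = tally.get(o.outcome_class, 0) + 1
            assert sum(tally.values()) == tstats.n_kept
            sam_path = outdir / "align" / f"{cond}.rep{rep}.sam"
            write_sam(outcomes, reference, sam_path)
            summary = pd.DataFrame(
                [{"read_id": o.read_id, "outcome": o.outcome_class,
                  "pass": o.record.pass_label if o.record else 0}
                 for o in outcomes]
            )
            summary.to_csv(
                outdir / "align" / f"{cond}.rep{rep}.outcomes.tsv",
                sep="\t", index=False,
            )
            log("align", condition=cond, replicate=rep, **tally,
                per_pass=astats.per_pass)

            stage = "extract"
            calls = [
                call_read(o.record, reference)
                for o in outcomes
                if o.outcome_class == "unique"
            ]
            kept, discarded = filter_artifact_reads(calls, config.extract)
            assert len(kept) + len(discarded) == tally.get("unique", 0)
            table = pileup(kept, reference, condition=cond, replicate=rep)
            write_site_outputs(table, outdir / "meth" / f"{cond}.rep{rep}")
            log("extract", condition=cond, replicate=rep,
                n_unique=len(calls), n_kept=len(kept),
                n_artifact_discarded=len(discarded), n_sites=len(table))
            tables.append(table)

        stage = "test"
        matrix = pd.concat(tables, ignore_index=True)
        matrix["site"] = (
            matrix["contig"] + ":" + matrix["pos"].astype(str) + ":" + matrix["strand"]
        )
        dep = call_dependent_sites(
            matrix,
            comparators=config.comparators,
            rescue=config.rescue,
            alpha=config.alpha,
            min_cov=config.min_cov,
        )
        labels = (
            matrix[matrix["label"] != ""]
            .drop_duplicates("site")[["site", "label"]]
            .set_index("site")["label"]
        )
        dep.insert(1, "label", dep["site"].map(labels).fillna(""))
        dep_path = outdir / "dependence_calls.tsv"
        dep.to_csv(dep_path, sep="\t", index=False, float_format="%.10g")
        matrix_path = outdir / "site_matrix.tsv"
        matrix.to_csv(matrix_path, sep="\t", index=False, float_format="%.10g")
        log("test", n_sites=int(matrix["site"].nunique()),
            n_tested=int((dep["verdict"] != "not_tested").sum()),
            n_dependent=int((dep["verdict"] == "dependent").sum()))
    except Exception as exc:  # partial outputs are retained on failure
        log("error", failed_stage=stage, message=str(exc))
        log_fh.close()
        raise PipelineError(stage, exc) from exc

    with open(outdir / "manifest_run.yaml", "w") as fh:
        yaml.safe_dump(
            {"config": config_to_dict(config), "seed": config.seed}, fh,
            sort_keys=True,
        )
    log_fh.close()
    return {
        "matrix": matrix,
        "dependence": dep,
        "dependence_path": dep_path,
        "matrix_path": matrix_path,
        "log_path": log_path,
        "outdir": outdir,
    }


def check_conservation(log_path) -> bool:
    """Verify read-count conservation identities from a run log."""
    with open(log_path) as fh:
        entries = [json.loads(line) for line in fh]
    by = lambda stage: {
        (e.get("condition"), e.get("replicate")): e
        for e in entries
        if e["stage"] == stage
    }
    trims, aligns, extracts = by("trim"), by("align"), by("extract")
    for key, t in trims.items():
        if t["n_in"] != t["n_kept"] + t["n_dropped"]:
            return False
        a = aligns[key]
        total = sum(
            a.get(k, 0)
            for k in ("unique", "ambiguous", "unaligned", "discarded_short")
        )
        if total != t["n_kept"]:
            return False
        e = extracts[key]
        if e["n_unique"] != a.get("unique", 0):
            return False
        if e["n_kept"] + e["n_artifact_discarded"] != e["n_unique"]:
            return False
    return True
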