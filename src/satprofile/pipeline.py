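"""Reproducible simulate → align → profile → group → tree pipeline runs.

A run is driven by a structured YAML/JSON configuration; every number in the
emitted report is recomputable from the emitted artifact files, and all
randomness flows from the single config seed through a named per-family
substream, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .align import (
    MonomerRecord,
    ScoringScheme,
    build_anchored_msa,
    global_align,
    percent_homology,
    trim_homologous_region,
)
from .fixtures import FIXTURE_CONFIGS
from .grouping import partition_profiles, profile_distance_matrix, to_newick, upgma
from .io import read_fasta, read_reference, write_fasta
from .profiling import build_profile_matrix, detect_alteration_columns
from .synthetic import default_flanks, generate_dataset, with_seed

logger = logging.getLogger("satprofile")


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"{where}: unknown key(s) {sorted(unknown)}")


@dataclass
class SimulateBlock:
    fixture: str
    background_rate: float = 0.0
    indel_rate: float = 0.0
    flanks: bool = False

    @classmethod
    def from_dict(cls, d: dict, where: str) -> "SimulateBlock":
        _check_keys(d, {"fixture", "background_rate", "indel_rate", "flanks"}, where)
        if "fixture" not in d:
            raise ValueError(f"{where}: simulate block needs a 'fixture'")
        if d["fixture"] not in FIXTURE_CONFIGS:
            raise ValueError(
                f"{where}: unknown fixture {d['fixture']!r}; "
                f"available: {sorted(FIXTURE_CONFIGS)}"
            )
        return cls(**d)


@dataclass
class InputBlock:
    fasta: str
    reference: str

    @classmethod
    def from_dict(cls, d: dict, where: str) -> "InputBlock":
        _check_keys(d, {"fasta", "reference"}, where)
        if "fasta" not in d:
            raise ValueError(f"{where}: input block needs 'fasta'")
        if "reference" not in d:
            raise ValueError(f"{where}: missing reference FASTA")
        return cls(**d)


@dataclass
class TrimParams:
    min_flank_identity: float = 0.5
    window: int = 10
    flank_lengths: tuple[int, int] | None = None

    @classmethod
    def from_dict(cls, d: dict, where: str) -> "TrimParams":
        _check_keys(d, {"min_flank_identity", "window", "flank_lengths"}, where)
        fl = d.get("flank_lengths")
        if fl is not None:
            fl = tuple(int(x) for x in fl)
            if len(fl) != 2:
                raise ValueError(f"{where}: flank_lengths must be [left, right]")
        return cls(
            min_flank_identity=float(d.get("min_flank_identity", 0.5)),
            window=int(d.get("window", 10)),
            flank_lengths=fl,
        )


@dataclass
class FamilyJob:
    name: str
    input: InputBlock | None = None
    simulate: SimulateBlock | None = None
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    trim: TrimParams = field(default_factory=TrimParams)
    tolerance: float = 0.0

    @classmethod
    def from_dict(cls, name: str, d: dict) -> "FamilyJob":
        where = f"families.{name}"
        _check_keys(d, {"input", "simulate", "scoring", "trim", "tolerance"}, where)
        has_input = "input" in d
        has_sim = "simulate" in d
        if has_input == has_sim:
            raise ValueError(f"{where}: exactly one of 'input' or 'simulate' is required")
        scoring = ScoringScheme()
        if "scoring" in d:
            _check_keys(
                d["scoring"], {"match", "mismatch", "gap_open", "gap_extend"}, f"{where}.scoring"
            )
            scoring = ScoringScheme(**{k: float(v) for k, v in d["scoring"].items()})
        return cls(
            name=name,
            input=InputBlock.from_dict(d["input"], f"{where}.input") if has_input else None,
            simulate=SimulateBlock.from_dict(d["simulate"], f"{where}.simulate") if has_sim else None,
            scoring=scoring,
            trim=TrimParams.from_dict(d.get("trim", {}), f"{where}.trim"),
            tolerance=float(d.get("tolerance", 0.0)),
        )


@dataclass
class RunConfig:
    families: dict[str, FamilyJob]
    seed: int = 0
    output_dir: str = "satprofile_out"
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        _check_keys(d, {"families", "seed", "output_dir", "log_level"}, "config")
        fams = d.get("families") or {}
        if not fams:
            raise ValueError("config: at least one family is required")
        families = {name: FamilyJob.from_dict(name, block) for name, block in fams.items()}
        return cls(
            families=families,
            seed=int(d.get("seed", 0)),
            output_dir=str(d.get("output_dir", "satprofile_out")),
            log_level=str(d.get("log_level", "INFO")),
        )

    def to_dict(self) -> dict:
        def drop_none(obj):
            if isinstance(obj, dict):
                return {k: drop_none(v) for k, v in obj.items() if v is not None}
            if isinstance(obj, (list, tuple)):
                return [drop_none(v) for v in obj]
            return obj

        out = {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
            "families": {},
        }
        for name, job in self.families.items():
            block = {
                "scoring": dataclasses.asdict(job.scoring),
                "trim": dataclasses.asdict(job.trim),
                "tolerance": job.tolerance,
            }
            if job.input is not None:
                block["input"] = dataclasses.asdict(job.input)
            if job.simulate is not None:
                block["simulate"] = dataclasses.asdict(job.simulate)
            out["families"][name] = drop_none(block)
        return out


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def family_seed(seed: int, family: str) -> int:
    """Named per-family substream of the run seed (stable across sessions)."""
    digest = hashlib.sha256(f"{seed}:{family}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class FamilyResult:
    """In-memory result of one family's analysis; artifacts derive from it."""

    name: str
    reference_id: str
    reference: str
    records: list[MonomerRecord]
    homology: dict[str, int | None]
    msa_fasta: str
    profile_tsv: str
    profile_json: str
    groups_json: str
    newick: str
    n_columns: int
    group_sizes: list[int]
    truth_tsv: str | None = None
    simulated_fasta: list[tuple[str, str]] | None = None


@dataclass
class RunReport:
    version: str
    config: dict
    families: dict[str, dict]

    def to_json(self) -> str:
        return json.dumps(
            {"version": self.version, "config": self.config, "families": self.families},
            indent=2,
        )


def _analyze_family(job: FamilyJob, seed: int) -> FamilyResult:
    truth_tsv = None
    simulated = None
    if job.simulate is not None:
        cfg = FIXTURE_CONFIGS[job.simulate.fixture]()
        cfg = dataclasses.replace(
            with_seed(cfg, family_seed(seed, job.name)),
            background_rate=job.simulate.background_rate,
            indel_rate=job.simulate.indel_rate,
        )
        if job.simulate.flanks:
            left, right = default_flanks()
            cfg = dataclasses.replace(cfg, left_flank=left, right_flank=right)
        pairs, truth = generate_dataset(cfg)
        reference_id = f"{job.name}_reference"
        reference = truth.reference
        records = [
            MonomerRecord(accession_id=a, species=a, family=job.name, sequence=s)
            for a, s in pairs
        ]
        truth_tsv = truth.to_tsv()
        simulated = pairs
        trim = job.trim
        if trim.flank_lengths is None and job.simulate.flanks:
            trim = dataclasses.replace(trim, flank_lengths=truth.flank_lengths)
    else:
        records = read_fasta(job.input.fasta, family=job.name)
        reference_id, reference = read_reference(job.input.reference)
        trim = job.trim

    alignments = []
    homology: dict[str, int | None] = {}
    for rec in records:
        aln = global_align(rec.sequence, reference, job.scoring, sample_id=rec.accession_id)
        aln = trim_homologous_region(
            aln,
            min_flank_identity=trim.min_flank_identity,
            window=trim.window,
            flank_lengths=trim.flank_lengths,
        )
        homology[rec.accession_id] = percent_homology(aln)
        alignments.append(aln)

    msa = build_anchored_msa(alignments, reference, reference_id=reference_id)
    columns = detect_alteration_columns(msa)
    matrix = build_profile_matrix(
        columns, msa.sample_ids, family=job.name, reference_id=reference_id
    )
    partition = partition_profiles(matrix, tolerance=job.tolerance)
    labels, D = profile_distance_matrix(matrix)
    tree = upgma(D, labels)
    logger.info(
        "%s: %d samples, %d alteration columns, %d groups",
        job.name,
        len(records),
        matrix.n_columns,
        len(partition.groups),
    )
    return FamilyResult(
        name=job.name,
        reference_id=reference_id,
        reference=reference,
        records=records,
        homology=homology,
        msa_fasta=msa.to_fasta(),
        profile_tsv=matrix.to_tsv(),
        profile_json=matrix.to_json(),
        groups_json=partition.to_json(),
        newick=to_newick(tree),
        n_columns=matrix.n_columns,
        group_sizes=partition.sizes,
        truth_tsv=truth_tsv,
        simulated_fasta=simulated,
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every configured family and emit artifacts under ``output_dir``.

    All families are computed in memory first; artifacts are written only once
    every stage has succeeded, so a failing run leaves no partial outputs.
    """
    import io as _io

    logging.getLogger("satprofile").setLevel(config.log_level.upper())
    # capture log lines produced during computation so run.log is complete,
    # while artifacts (run.log included) appear only after a fully clean run
    buf = _io.StringIO()
    mem = logging.StreamHandler(buf)
    mem.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(mem)
    try:
        results: list[FamilyResult] = []
        for name, job in config.families.items():
            try:
                results.append(_analyze_family(job, config.seed))
            except Exception as exc:
                raise RuntimeError(f"family {name}: {exc}") from exc
    finally:
        logger.removeHandler(mem)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run.log").write_text(buf.getvalue())
    fh = logging.FileHandler(out / "run.log", mode="a")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(fh)
    try:
        report_families = {}
        for res in results:
            prefix = out / res.name
            if res.simulated_fasta is not None:
                write_fasta(res.simulated_fasta, f"{prefix}_samples.fasta")
                write_fasta([(res.reference_id, res.reference)], f"{prefix}_reference.fasta")
                Path(f"{prefix}_truth.tsv").write_text(res.truth_tsv)
            Path(f"{prefix}_msa.fasta").write_text(res.msa_fasta)
            Path(f"{prefix}_profile.tsv").write_text(res.profile_tsv)
            Path(f"{prefix}_profile.json").write_text(res.profile_json)
            Path(f"{prefix}_groups.json").write_text(res.groups_json)
            Path(f"{prefix}_tree.nwk").write_text(res.newick + "\n")
            report_families[res.name] = {
                "n_samples": len(res.records),
                "homology_percent": res.homology,
                "n_alteration_columns": res.n_columns,
                "group_sizes": res.group_sizes,
                "msa_columns": len(res.reference),
                "tree_file": str(f"{prefix}_tree.nwk"),
                "profile_file": str(f"{prefix}_profile.tsv"),
            }
        report = RunReport(
            version=__version__, config=config.to_dict(), families=report_families
        )
        (out / "report.json").write_text(report.to_json())
        return report
    finally:
        logger.removeHandler(fh)
        fh.close()
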