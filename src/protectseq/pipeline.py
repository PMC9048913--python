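"""Pipeline orchestration: simulate -> quantify -> difftest -> classify -> circ.

Every stage reads the previous stage's files, so each is independently
re-runnable; a run's configuration is copied verbatim into its output
directory and a manifest records per-stage outputs, hashes and wall time.
Stage-local random generators derive from the master seed by stable keys, so
rerunning one stage reproduces the randomness of the full run.
"""

from __future__ import annotations

import json
import shutil
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import circrna, difftest, io, localization, mapping, presets, simulate
from ._util import sha256_file

TREATMENTS_BY_PRESET = {
    "default": ("C", "R", "TR"),
    "fig4": ("C", "R", "TR"),
    "fig4-tas": ("C", "R", "TR"),
    "rnaser": ("C", "RR"),
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 1
    preset: str = "default"
    depth: int | None = None          # None -> preset default
    replicates: int = 3
    alpha: float = localization.DEFAULT_ALPHA
    rpm_threshold: float = 1.0
    rpm_comparator: str = ">"
    min_overlap: int = circrna.DEFAULT_MIN_OVERLAP
    flank: int | None = None          # None -> read length
    tau: float = localization.DEFAULT_TAU
    outdir: str = "protectseq_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def generator_config(self) -> simulate.GeneratorConfig:
        overrides = {"n_replicates": self.replicates}
        if self.depth is not None:
            overrides["depth"] = self.depth
        return presets.make_config(self.preset, seed=self.seed, **overrides)


@dataclass
class RunManifest:
    config_hash: str
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, outdir: Path, files: list[Path], t0: float) -> None:
        self.stages.append({
            "stage": stage,
            "seconds": round(time.time() - t0, 3),
            "files": {str(p.relative_to(outdir)): sha256_file(p) for p in files},
        })

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "stages": self.stages}, fh, indent=1)


def _stage_simulate(cfg: RunConfig, outdir: Path) -> list[Path]:
    gconf = cfg.generator_config()
    treatments = TREATMENTS_BY_PRESET[cfg.preset]
    data = simulate.simulate_dataset(gconf, treatments)
    ref = data["reference"]
    files = []

    def save(name, fn):
        p = outdir / name
        fn(p)
        files.append(p)

    save("genome.fa", lambda p: io.write_genome_fasta(ref.chromosomes, p))
    save("features.gff3", lambda p: io.write_gff3(ref.features, p))
    save("circles.tsv", lambda p: io.write_circles_tsv(ref.circles, p))
    save("species.tsv", lambda p: io.write_table(simulate.species_table(data["species"]), p,
                                                 index=False))
    save("truth_counts.tsv", lambda p: io.write_table(data["truth"], p))
    save("samplesheet.tsv", lambda p: io.write_table(data["samplesheet"], p, index=False))
    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    for rs in data["readsets"]:
        p = reads_dir / f"{rs.sample_id}.fastq"
        io.write_fastq(rs, p)
        files.append(p)
    return files


def _load_readsets(outdir: Path) -> list[simulate.ReadSet]:
    sheet = pd.read_csv(outdir / "samplesheet.tsv", sep="\t")
    readsets = []
    for row in sheet.itertuples(index=False):
        counts = io.read_fastq_counts(outdir / "reads" / f"{row.sample_id}.fastq")
        reads = pd.DataFrame(
            {"sequence": list(counts), "species_id": "NA", "compartment": "NA",
             "count": list(counts.values())})
        readsets.append(simulate.ReadSet(row.sample_id, row.treatment, row.replicate, reads))
    return readsets


def _stage_quantify(cfg: RunConfig, outdir: Path) -> list[Path]:
    ref = simulate.Reference(io.read_genome_fasta(outdir / "genome.fa"),
                             io.read_gff3(outdir / "features.gff3"))
    readsets = _load_readsets(outdir)
    if sum(rs.n_reads for rs in readsets) == 0:
        raise ValueError("zero mapped reads: no sequencing output to quantify")
    gconf = cfg.generator_config()
    q = mapping.count_and_normalize(readsets, ref, max_len=max(mapping.MAX_READ_LEN,
                                                               gconf.read_length))
    if q.flags:
        raise ValueError(f"zero mapped reads in samples: {q.flags}")
    files = []
    for name, df in [("counts.tsv", q.counts), ("rpm.tsv", q.rpm),
                     ("spectrum.tsv", q.spectrum), ("category_rpm.tsv", q.category_rpm),
                     ("subfeature_rpm.tsv", q.subfeature_rpm)]:
        io.write_table(df, outdir / name)
        files.append(outdir / name)
    return files


def _stage_difftest(cfg: RunConfig, outdir: Path) -> list[Path]:
    counts = io.read_table(outdir / "counts.tsv").drop(index=mapping.UNANNOTATED,
                                                       errors="ignore")
    rpm = io.read_table(outdir / "rpm.tsv").drop(index=mapping.UNANNOTATED, errors="ignore")
    sheet = pd.read_csv(outdir / "samplesheet.tsv", sep="\t")
    retained = localization.filter_by_rpm(rpm, cfg.rpm_threshold,
                                          comparator=cfg.rpm_comparator)
    results = difftest.run_contrasts(counts.loc[retained], sheet)
    files = []
    for label, res in results.items():
        p = outdir / f"contrast_{label}.tsv"
        io.write_table(res, p)
        files.append(p)
    return files


def _stage_classify(cfg: RunConfig, outdir: Path) -> list[Path]:
    contrasts = {}
    for label in localization.CONTRAST_ORDER:
        p = outdir / f"contrast_{label}.tsv"
        if not p.exists():
            raise FileNotFoundError(f"missing difftest output {p.name}")
        contrasts[label] = io.read_table(p)
    calls = localization.classify_table(contrasts, alpha=cfg.alpha)
    files = []
    io.write_table(calls, outdir / "localization.tsv")
    files.append(outdir / "localization.tsv")

    cat_rpm = io.read_table(outdir / "category_rpm.tsv")
    sheet = pd.read_csv(outdir / "samplesheet.tsv", sep="\t")
    means = {}
    for t in sheet["treatment"].unique():
        cols = sheet.loc[sheet["treatment"] == t, "sample_id"]
        means[t] = cat_rpm[cols].mean(axis=1)
    means = pd.DataFrame(means)
    if {"C", "R", "TR"} <= set(means.columns):
        profile = localization.category_protection_profile(means, tau=cfg.tau)
        io.write_table(profile, outdir / "category_profile.tsv")
        files.append(outdir / "category_profile.tsv")

    species_path = outdir / "species.tsv"
    if species_path.exists():
        sp = pd.read_csv(species_path, sep="\t")
        truth = sp[sp["planted_class"].notna() & (sp["planted_class"] != "")]
        if len(truth):
            truth_s = truth.set_index("feature_id")["planted_class"]
            confusion, recall = localization.recover_localization(calls["call"], truth_s)
            io.write_table(confusion, outdir / "confusion.tsv")
            files.append(outdir / "confusion.tsv")
    return files


def _stage_circ(cfg: RunConfig, outdir: Path) -> list[Path]:
    circles = io.read_circles_tsv(outdir / "circles.tsv")
    if not len(circles):
        return []
    ref = simulate.Reference(io.read_genome_fasta(outdir / "genome.fa"),
                             io.read_gff3(outdir / "features.gff3"))
    gconf = cfg.generator_config()
    flank = cfg.flank or gconf.read_length
    lib = circrna.build_junction_library(circles, ref, flank, cfg.min_overlap)
    index = mapping.build_index(ref)
    files = []
    with open(outdir / "junctions.fa", "w") as fh:
        for j in lib.junctions:
            fh.write(f">{j.circ_id}\n{j.junction_seq}\n")
    files.append(outdir / "junctions.fa")
    rows = []
    for rs in _load_readsets(outdir):
        rep = circrna.circ_fraction(rs, lib, index, ref)
        rows.append((rs.sample_id, rs.treatment, rep.junction_reads, rep.total_reads,
                     rep.percentage))
    df = pd.DataFrame(rows, columns=["sample_id", "treatment", "junction_reads",
                                     "total_reads", "percentage"])
    io.write_table(df, outdir / "circ_report.tsv", index=False)
    files.append(outdir / "circ_report.tsv")
    return files


STAGES = [
    ("simulate", _stage_simulate),
    ("quantify", _stage_quantify),
    ("difftest", _stage_difftest),
    ("classify", _stage_classify),
    ("circ", _stage_circ),
]


def run_all(cfg: RunConfig) -> RunManifest:
    """Run every stage in order; on failure, quarantine outputs under failed/."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "run.yaml")
    manifest = RunManifest(config_hash=sha256_file(outdir / "run.yaml"))
    skip = {"difftest", "classify"} if cfg.preset == "rnaser" else set()
    for stage, fn in STAGES:
        if stage in skip:
            continue
        t0 = time.time()
        try:
            files = fn(cfg, outdir)
        except Exception as exc:
            failed = outdir / "failed"
            failed.mkdir(exist_ok=True)
            for p in outdir.iterdir():
                if p.name not in ("failed", "run.yaml"):
                    shutil.move(str(p), failed / p.name)
            raise StageError(stage, exc) from exc
        manifest.record(stage, outdir, files, t0)
    summarize(outdir)
    manifest.write(outdir / "manifest.json")
    return manifest


def summarize(outdir) -> list[Path]:
    """Figure-shaped report tables from a completed run."""
    outdir = Path(outdir)
    sheet_path = outdir / "samplesheet.tsv"
    if not sheet_path.exists():
        raise FileNotFoundError("missing simulate output samplesheet.tsv")
    sheet = pd.read_csv(sheet_path, sep="\t")
    reports = []

    def by_treatment(df):
        out = {}
        for t in sheet["treatment"].unique():
            cols = [c for c in sheet.loc[sheet["treatment"] == t, "sample_id"] if c in df]
            out[t] = df[cols].mean(axis=1)
        return pd.DataFrame(out)

    for src, dst, normalize in [("spectrum.tsv", "report_spectrum_by_treatment.tsv", False),
                                ("category_rpm.tsv", "report_category_share_by_treatment.tsv",
                                 True)]:
        p = outdir / src
        if not p.exists():
            raise FileNotFoundError(f"missing quantify output {src}")
        df = by_treatment(io.read_table(p))
        if normalize:
            df = df / df.sum(axis=0)
        io.write_table(df, outdir / dst)
        reports.append(outdir / dst)

    loc = outdir / "localization.tsv"
    if loc.exists():
        shutil.copyfile(loc, outdir / "report_feature_localization.tsv")
        reports.append(outdir / "report_feature_localization.tsv")
    circ = outdir / "circ_report.tsv"
    if circ.exists():
        shutil.copyfile(circ, outdir / "report_circ_fraction.tsv")
        reports.append(outdir / "report_circ_fraction.tsv")
    return reports
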