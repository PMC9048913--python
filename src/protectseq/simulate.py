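"""Simulation of the enzymatic protection assay on extracellular RNA.

The model: an apoplastic particle pellet contains a population of RNA species,
each partitioned across three physical compartments —

* ``inside_EV``          encapsulated in extracellular vesicles, shielded from
                         both protease and RNase;
* ``outside_protected``  outside vesicles but bound by RNA-binding proteins,
                         shielded from RNase A alone (fully, or partially as a
                         bound-protein "footprint" of 16-17 nt);
* ``outside_naked``      free RNA, degraded by any RNase treatment.

Enzymatic treatments are modelled as operators on a pool of fragments:

* ``C``   buffer control — degrades nothing;
* ``R``   RNase A — removes naked RNA, trims footprint-protected RNA down to
          its protein footprint, spares vesicle cargo and fully protein-bound RNA;
* ``TR``  trypsin then RNase A — removes *all* RNA outside vesicles;
* ``RR``  RNase R — a 3'->5' exoribonuclease that removes linear RNA (up to a
          small escape fraction) regardless of compartment while sparing
          covalently closed circles.

Treatment operators act on expected fragment weights (the infinite-molecule
limit); all stochasticity enters at sequencing, where replicate libraries are
drawn with a per-species Gamma multiplier (negative-binomial overdispersion)
followed by a multinomial read draw at fixed depth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd

from ._util import child_rng, is_dna, revcomp

CATEGORIES = (
    "rRNA", "tRNA", "miRNA", "TAS", "snRNA", "snoRNA",
    "polIV", "TE", "mRNA", "intergenic", "circRNA",
)
SUBFEATURES = ("none", "five_utr", "cds", "intron", "three_utr")
COMPARTMENTS = ("inside_EV", "outside_protected", "outside_naked")
TREATMENT_NAMES = ("C", "R", "TR", "RR")


class ConfigurationError(ValueError):
    """Invalid generator or pipeline configuration."""


class GenerationError(RuntimeError):
    """Inconsistent synthetic annotation (overlaps, out-of-bounds, collisions)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureInterval:
    """A genomic feature; 0-based half-open internally, 1-based inclusive on disk."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    category: str
    subfeature: str = "none"
    parent: str | None = None

    def __post_init__(self):
        if not self.start < self.end:
            raise GenerationError(f"{self.feature_id}: start must be < end")
        if self.category not in CATEGORIES:
            raise GenerationError(f"{self.feature_id}: unknown category {self.category}")
        if self.subfeature != "none" and self.category != "mRNA":
            raise GenerationError(f"{self.feature_id}: subfeatures are mRNA-only")
        if self.strand not in "+-":
            raise GenerationError(f"{self.feature_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Reference:
    """A toy genome plus its feature annotation."""

    chromosomes: dict[str, str]
    features: list[FeatureInterval]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name, seq in self.chromosomes.items():
            if not is_dna(seq):
                raise GenerationError(f"chromosome {name}: alphabet must be ACGT")
        for f in self.features:
            if f.chrom not in self.chromosomes:
                raise GenerationError(f"{f.feature_id}: unknown chromosome {f.chrom}")
            if f.end > len(self.chromosomes[f.chrom]):
                raise GenerationError(f"{f.feature_id}: interval exceeds chromosome")

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.chromosomes[chrom][start:end]
        return seq if strand == "+" else revcomp(seq)

    @property
    def circles(self) -> list[FeatureInterval]:
        return [f for f in self.features if f.category == "circRNA"]


@dataclass(frozen=True)
class RnaSpecies:
    """One transcript/fragment population with compartment structure."""

    species_id: str
    source_feature: str
    category: str
    length: int
    circular: bool
    compartment_fracs: tuple[float, float, float]  # inside_EV, outside_protected, outside_naked
    protection_mode: str  # full | footprint | none
    base_abundance: float
    sequence: str
    footprint_range: tuple[int, int] | None = None
    planted_class: str | None = None

    def __post_init__(self):
        if abs(sum(self.compartment_fracs) - 1.0) > 1e-9:
            raise GenerationError(f"{self.species_id}: compartment fractions must sum to 1")
        if any(f < 0 or f > 1 for f in self.compartment_fracs):
            raise GenerationError(f"{self.species_id}: fractions outside [0,1]")
        if self.base_abundance <= 0:
            raise GenerationError(f"{self.species_id}: base abundance must be > 0")
        if self.protection_mode == "footprint":
            if self.circular:
                raise GenerationError(f"{self.species_id}: circular species cannot footprint")
            if self.footprint_range is None or self.footprint_range[1] >= self.length:
                raise GenerationError(f"{self.species_id}: footprint must be shorter than species")
        if len(self.sequence) != self.length:
            raise GenerationError(f"{self.species_id}: sequence/length mismatch")


@dataclass(frozen=True)
class TreatmentSpec:
    """One enzymatic treatment as a degradation rule set."""

    name: str
    degrade_outside_naked: bool = False
    degrade_outside_protected: str = "no"  # no | footprint | yes
    degrade_insideEV: bool = False
    degrade_linear: bool = False  # RNase R only
    linear_escape_prob: float = 0.0

    @classmethod
    def named(cls, name: str, linear_escape_prob: float = 0.02) -> "TreatmentSpec":
        if name == "C":
            return cls("C")
        if name == "R":
            return cls("R", degrade_outside_naked=True, degrade_outside_protected="footprint")
        if name == "TR":
            return cls("TR", degrade_outside_naked=True, degrade_outside_protected="yes")
        if name == "RR":
            return cls("RR", degrade_linear=True, linear_escape_prob=linear_escape_prob)
        raise ConfigurationError(f"unknown treatment {name!r}; expected one of {TREATMENT_NAMES}")


@dataclass(frozen=True)
class Fragment:
    """A molecule class in the pool: a sequence with an expected molar weight."""

    species_id: str
    compartment: str
    sequence: str
    length: int
    circular_origin: bool
    weight: float
    protection_mode: str = "full"
    footprint_range: tuple[int, int] | None = None


@dataclass
class FragmentPool:
    entries: list[Fragment]

    @property
    def total_weight(self) -> float:
        return float(sum(e.weight for e in self.entries))

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ReadSet:
    """Sequenced reads of one replicate library, aggregated by identical sequence.

    ``reads`` has columns sequence / species_id / compartment / count; every row
    carries its truth labels, and :meth:`iter_reads` expands to per-read records
    for FASTQ export.
    """

    sample_id: str
    treatment: str
    replicate: int
    reads: pd.DataFrame

    @property
    def n_reads(self) -> int:
        return int(self.reads["count"].sum()) if len(self.reads) else 0

    def iter_reads(self) -> Iterator[tuple[str, str, str, str]]:
        i = 0
        for row in self.reads.itertuples(index=False):
            for _ in range(int(row.count)):
                yield f"{self.sample_id}_{i}", row.sequence, row.species_id, row.compartment
                i += 1

    def truth_counts(self) -> pd.Series:
        if not len(self.reads):
            return pd.Series(dtype=int, name=self.sample_id)
        out = self.reads.groupby("species_id")["count"].sum()
        out.name = self.sample_id
        return out


@dataclass
class GeneratorConfig:
    seed: int = 1
    preset: str = "default"
    depth: int = 1_000_000
    n_replicates: int = 3  # three independent biological replicates
    overdispersion: float = 0.05
    read_length: int = 34
    linear_escape_prob: float = 0.02

    def __post_init__(self):
        if self.depth < 0:
            raise ConfigurationError("depth must be >= 0")
        if self.overdispersion < 0:
            raise ConfigurationError("overdispersion must be >= 0")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_reference(config: GeneratorConfig) -> tuple[Reference, list[RnaSpecies]]:
    """Generate the toy genome, annotation and RNA population for a preset.

    Deterministic for a given seed. See :mod:`protectseq.presets` for the
    preset tables.
    """
    from . import presets

    builder = presets.PRESETS.get(config.preset)
    if builder is None:
        raise ConfigurationError(
            f"unknown preset {config.preset!r}; available: {sorted(presets.PRESETS)}")
    return builder(config)


def initial_pool(species: list[RnaSpecies], read_length: int) -> FragmentPool:
    """Expand species into the untreated fragment pool.

    Species no longer than the sequencing length cap contribute one fragment per
    occupied compartment. Longer species shed windows of ``read_length`` at
    every offset (wrapping for circles), weight split uniformly — a flat
    fragmentation model.
    """
    entries: list[Fragment] = []
    for sp in species:
        for comp, frac in zip(COMPARTMENTS, sp.compartment_fracs):
            if frac <= 0:
                continue
            w = sp.base_abundance * frac
            if sp.length <= read_length:
                entries.append(Fragment(sp.species_id, comp, sp.sequence, sp.length,
                                        sp.circular, w, sp.protection_mode, sp.footprint_range))
            elif sp.circular:
                doubled = sp.sequence + sp.sequence
                n = sp.length
                for off in range(n):
                    entries.append(Fragment(sp.species_id, comp, doubled[off:off + read_length],
                                            read_length, True, w / n, sp.protection_mode, None))
            else:
                n = sp.length - read_length + 1
                for off in range(n):
                    entries.append(Fragment(sp.species_id, comp, sp.sequence[off:off + read_length],
                                            read_length, False, w / n, sp.protection_mode,
                                            sp.footprint_range))
    return FragmentPool(entries)


def _footprint_products(frag: Fragment) -> list[Fragment]:
    lo, hi = frag.footprint_range
    lengths = range(lo, hi + 1)
    per_len = frag.weight / len(lengths)
    out = []
    for l in lengths:
        n_off = frag.length - l + 1
        for off in range(n_off):
            out.append(replace(frag, sequence=frag.sequence[off:off + l], length=l,
                               weight=per_len / n_off))
    return out


def apply_treatment(pool: FragmentPool, t: TreatmentSpec, seed: int | None = None) -> FragmentPool:
    """Apply one enzymatic treatment to a fragment pool.

    Operates on expected weights, so the result is deterministic; ``seed`` is
    accepted for interface stability but unused. RNase A ("R") converts
    footprint-mode protein-protected fragments into the uniform mixture over
    footprint lengths and offsets.
    """
    if t.name not in TREATMENT_NAMES:
        raise ConfigurationError(f"unknown treatment {t.name!r}")
    out: list[Fragment] = []
    for frag in pool.entries:
        if t.degrade_linear:  # RNase R
            if frag.circular_origin:
                out.append(frag)
            elif t.linear_escape_prob > 0:
                out.append(replace(frag, weight=frag.weight * t.linear_escape_prob))
            continue
        if frag.compartment == "inside_EV":
            if not t.degrade_insideEV:
                out.append(frag)
            continue
        if frag.compartment == "outside_naked":
            if not t.degrade_outside_naked:
                out.append(frag)
            continue
        # outside_protected
        if t.degrade_outside_protected == "no":
            out.append(frag)
        elif t.degrade_outside_protected == "footprint":
            if frag.protection_mode == "full":
                out.append(frag)
            elif frag.protection_mode == "footprint":
                out.extend(_footprint_products(frag))
            # mode "none": protein shield absent -> degraded
        # "yes": degraded
    return FragmentPool(out)


def sample_libraries(
    pool: FragmentPool,
    config: GeneratorConfig,
    treatment: str = "C",
    rng: np.random.Generator | None = None,
    species_universe: list[str] | None = None,
) -> tuple[list[ReadSet], pd.DataFrame]:
    """Draw replicate sequencing libraries from a (treated) fragment pool.

    Each biological replicate is one harvest of the extracellular RNA pool:
    every species' weight carries a Gamma multiplier with mean 1 and variance
    ``overdispersion`` (the gamma-Poisson route to a negative binomial) that is
    a property of the *replicate*, not of the treatment — replicate r's
    multipliers are derived from the master seed and r alone, so aliquots of
    the same replicate under different treatments share them, as they do in
    the paired assay design. Sequencing then draws ``depth`` reads
    multinomially over fragments, independently per library. Reads are the
    fragment sequence truncated at the length cap. Pass ``species_universe``
    (the full species id list) so that multipliers stay aligned when a
    treatment removes species entirely. Returns the read sets and the truth
    count matrix (species x sample).
    """
    if config.depth > 0 and (len(pool) == 0 or pool.total_weight <= 0):
        raise GenerationError(f"cannot sample {config.depth} reads from an empty pool")

    pool_species = sorted({e.species_id for e in pool.entries})
    universe = sorted(species_universe) if species_universe is not None else pool_species
    sp_index = {s: i for i, s in enumerate(universe)}
    weights = np.array([e.weight for e in pool.entries], dtype=float)
    sp_of_entry = np.array([sp_index[e.species_id] for e in pool.entries], dtype=int)
    cap = config.read_length

    readsets: list[ReadSet] = []
    truth_cols = []
    for rep in range(1, config.n_replicates + 1):
        sample_id = f"{treatment}{rep}"
        if config.depth == 0 or len(pool) == 0:
            reads = pd.DataFrame(columns=["sequence", "species_id", "compartment", "count"])
            rs = ReadSet(sample_id, treatment, rep, reads)
            readsets.append(rs)
            truth_cols.append(rs.truth_counts())
            continue
        if config.overdispersion > 0:
            shape = 1.0 / config.overdispersion
            rep_rng = child_rng(config.seed, "biorep", rep)
            g = rep_rng.gamma(shape, config.overdispersion, size=len(universe))
        else:
            g = np.ones(len(universe))
        seq_rng = rng if rng is not None else child_rng(config.seed, "sequencing",
                                                       treatment, rep)
        p = weights * g[sp_of_entry]
        p = p / p.sum()
        counts = seq_rng.multinomial(config.depth, p)
        nz = np.nonzero(counts)[0]
        reads = pd.DataFrame({
            "sequence": [pool.entries[i].sequence[:cap] for i in nz],
            "species_id": [pool.entries[i].species_id for i in nz],
            "compartment": [pool.entries[i].compartment for i in nz],
            "count": counts[nz],
        })
        reads = (reads.groupby(["sequence", "species_id", "compartment"], as_index=False)["count"]
                 .sum())
        rs = ReadSet(sample_id, treatment, rep, reads)
        readsets.append(rs)
        truth_cols.append(rs.truth_counts())

    truth = pd.concat(truth_cols, axis=1).fillna(0).astype(int)
    truth = truth.reindex(pool_species, fill_value=0)
    truth.index.name = "species_id"
    return readsets, truth


def simulate_dataset(
    config: GeneratorConfig,
    treatments: tuple[str, ...] = ("C", "R", "TR"),
) -> dict:
    """Run the full simulation: reference, per-treatment pools, libraries, truth.

    Returns a dict with keys reference, species, pools, readsets (flat list),
    truth (species x sample counts), and samplesheet.
    """
    reference, species = build_reference(config)
    pool0 = initial_pool(species, config.read_length)
    readsets: list[ReadSet] = []
    truths = []
    pools = {}
    universe = [sp.species_id for sp in species]
    for t_name in treatments:
        spec = TreatmentSpec.named(t_name, config.linear_escape_prob)
        treated = apply_treatment(pool0, spec)
        pools[t_name] = treated
        rs, truth = sample_libraries(treated, config, treatment=t_name,
                                     species_universe=universe)
        readsets.extend(rs)
        truths.append(truth)
    truth = pd.concat(truths, axis=1).fillna(0).astype(int)
    samplesheet = pd.DataFrame(
        [(r.sample_id, r.treatment, r.replicate) for r in readsets],
        columns=["sample_id", "treatment", "replicate"],
    )
    return {
        "reference": reference,
        "species": species,
        "pools": pools,
        "readsets": readsets,
        "truth": truth,
        "samplesheet": samplesheet,
    }


def species_table(species: list[RnaSpecies]) -> pd.DataFrame:
    """Ground-truth table of the simulated RNA population."""
    rows = []
    for sp in species:
        rows.append({
            "species_id": sp.species_id,
            "feature_id": sp.source_feature,
            "category": sp.category,
            "length": sp.length,
            "circular": sp.circular,
            "frac_inside_EV": sp.compartment_fracs[0],
            "frac_outside_protected": sp.compartment_fracs[1],
            "frac_outside_naked": sp.compartment_fracs[2],
            "protection_mode": sp.protection_mode,
            "base_abundance": sp.base_abundance,
            "planted_class": sp.planted_class or "",
        })
    return pd.DataFrame(rows)
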