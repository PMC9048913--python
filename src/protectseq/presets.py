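"""Versioned generator presets: the planted study conditions.

Each preset builds a toy genome plus an RNA population whose compartment
structure plants a known truth:

``default``
    A mixed apoplastic small-RNA pool. Class weights are chosen so the control
    libraries peak at 21, 22 and 31 nt (miRNA/tasiRNA, siRNA/TE, and Pol IV
    precursor lengths), RNase A alone leaves twin footprint peaks at 16-17 nt
    (protein footprints on the 31-nt Pol IV precursors), and trypsin + RNase A
    leaves the vesicle-enclosed tiny-RNA peaks at 10 and 12 nt.

``fig4``
    427 mature miRNAs of which 94 exceed the 1-RPM detection filter. The 94
    split into planted localization clades: 7 inside vesicles, 10 both inside
    and outside (3 of them with a TR-vs-R surplus), 24 outside and
    protein-protected, 21 outside and unprotected, and 32 with no differential
    signal — 62 differential in at least one contrast. The non-differential
    class is the median feature of every treatment column, anchoring
    median-of-ratios normalization.

``fig4-tas``
    1581 tasiRNAs of which 27 exceed the 5-RPM filter (16 protein-protected,
    11 unprotected; none vesicle-enclosed).

``rnaser``
    An RNase R pool: six circular RNAs (60-76 nt circles) carrying 60% of the
    molar weight, shedding 50-nt windows at every rotational offset, plus
    linear RNA with a 2% escape probability. About 45% of post-digestion reads
    span a back-splice junction with >= 10 nt on each side.

All presets draw genome sequence from the seeded generator, so the *sequences*
change with the seed while the planted counts and effect structure do not.
"""

from __future__ import annotations

import numpy as np

from ._util import child_rng, revcomp
from .simulate import (
    CATEGORIES,
    FeatureInterval,
    GenerationError,
    GeneratorConfig,
    Reference,
    RnaSpecies,
)

# weight of each tiny-RNA length class (split evenly across the 11 source
# categories); 10 and 12 nt dominate, mirroring the vesicle cargo spectrum
TYRNA_LENGTH_WEIGHTS = {10: 0.024, 11: 0.007, 12: 0.019, 13: 0.006,
                        14: 0.005, 15: 0.005, 16: 0.005, 17: 0.004}

# per-preset study conditions (merged into GeneratorConfig by make_config)
PRESET_DEFAULTS = {
    "default": {"depth": 1_000_000, "read_length": 34},
    "fig4": {"depth": 1_000_000, "read_length": 34},
    "fig4-tas": {"depth": 1_000_000, "read_length": 34},
    "rnaser": {"depth": 100_000, "read_length": 50},
}


def make_config(preset: str, seed: int = 1, **overrides) -> GeneratorConfig:
    """A GeneratorConfig carrying the preset's documented depth and read length."""
    if preset not in PRESET_DEFAULTS:
        from .simulate import ConfigurationError
        raise ConfigurationError(f"unknown preset {preset!r}")
    kw = dict(PRESET_DEFAULTS[preset])
    kw.update(overrides)
    return GeneratorConfig(seed=seed, preset=preset, **kw)


def _random_genome(rng, n_chrom: int, chrom_len: int) -> dict[str, str]:
    bases = np.array(list("ACGT"))
    return {
        f"chr{i + 1}": "".join(bases[rng.integers(0, 4, size=chrom_len)])
        for i in range(n_chrom)
    }


class _Placer:
    """Places non-overlapping features across chromosomes with random gaps."""

    def __init__(self, genome: dict[str, str], rng):
        self.genome = genome
        self.rng = rng
        self.cursor = {c: 0 for c in genome}

    def place(self, length: int) -> tuple[str, int, int]:
        chrom = min(self.cursor, key=lambda c: self.cursor[c])
        start = self.cursor[chrom] + int(self.rng.integers(60, 150))
        end = start + length
        if end > len(self.genome[chrom]):
            raise GenerationError("toy genome exhausted; enlarge chromosomes")
        self.cursor[chrom] = end
        return chrom, start, end


def _locus(placer, features, feature_id, category, length, rng, subfeature="none",
           parent=None, strand=None):
    chrom, start, end = placer.place(length)
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    f = FeatureInterval(feature_id, chrom, start, end, strand, category, subfeature, parent)
    features.append(f)
    return f


def _species_for(feature, ref, species_id, fracs, weight, mode="full",
                 footprint=None, circular=False, planted=None, length=None, offset=0):
    length = feature.length if length is None else length
    seq = ref.fetch(feature.chrom, feature.start + offset, feature.start + offset + length,
                    feature.strand)
    return RnaSpecies(species_id, feature.feature_id, feature.category, length, circular,
                      fracs, mode, weight, seq, footprint, planted)


def _check_circle_junctions(ref: Reference, circles, flank: int = 25) -> None:
    """Back-splice junction cores must be absent from the linear genome."""
    for c in circles:
        seq = ref.fetch(c.chrom, c.start, c.end, c.strand)
        core = seq[-flank:] + seq[:flank]
        for chrom_seq in ref.chromosomes.values():
            if core in chrom_seq or revcomp(core) in chrom_seq:
                raise GenerationError(f"junction of {c.feature_id} occurs in linear genome")


# ---------------------------------------------------------------------------
# default preset
# ---------------------------------------------------------------------------

# (category, n_species, length cycle, total weight, fracs, mode, footprint)
_DEFAULT_CLASSES = [
    ("miRNA", 35, [21], 0.110, (0.02, 0.42, 0.56), "full", None),
    ("TAS", 30, [21], 0.130, (0.01, 0.15, 0.84), "full", None),
    ("TAS", 25, [22], 0.100, (0.01, 0.15, 0.84), "full", None),
    ("TE", 25, [22], 0.100, (0.01, 0.40, 0.59), "full", None),
    ("polIV", 40, [31], 0.185, (0.02, 0.93, 0.05), "footprint", (16, 17)),
    ("rRNA", 21, list(range(24, 31)), 0.115, (0.08, 0.42, 0.50), "full", None),
    ("tRNA", 26, list(range(18, 31)), 0.050, (0.40, 0.05, 0.55), "full", None),
    ("snRNA", 4, [24], 0.015, (0.05, 0.75, 0.20), "full", None),
    ("snoRNA", 3, [26], 0.010, (0.05, 0.75, 0.20), "full", None),
    ("intergenic", 12, [20, 21, 22, 23], 0.020, (0.02, 0.18, 0.80), "full", None),
]

_TYRNA_FRACS = (0.85, 0.05, 0.10)

_GENE_PARTS = [("five_utr", 60), ("cds", 120), ("intron", 90), ("cds", 120), ("three_utr", 60)]


def build_default(config: GeneratorConfig) -> tuple[Reference, list[RnaSpecies]]:
    rng = child_rng(config.seed, "reference", "default")
    genome = _random_genome(rng, 5, 50_000)
    placer = _Placer(genome, rng)
    features: list[FeatureInterval] = []
    ref = Reference(genome, [])

    species: list[RnaSpecies] = []
    hosts: dict[str, FeatureInterval] = {}

    for ci, (cat, n, lengths, total_w, fracs, mode, fp) in enumerate(_DEFAULT_CLASSES):
        w = total_w / n
        for i in range(n):
            length = lengths[i % len(lengths)]
            fid = f"{cat}_{ci}_{i}"
            f = _locus(placer, features, fid, cat, length, rng)
            hosts.setdefault(cat, f)
            ref.features = features
            species.append(_species_for(f, ref, f"sp_{fid}", fracs, w, mode, fp))

    # protein-coding genes with sub-feature structure; fragments 18-28 nt
    gene_total_w = 0.080
    n_frag = 24
    frag_w = gene_total_w / n_frag
    frag_lengths = list(range(18, 29))
    part_cycle = ["five_utr", "cds", "intron", "three_utr"]
    gene_parts: list[tuple[FeatureInterval, str]] = []
    for g in range(6):
        gid = f"gene_{g}"
        gene_len = sum(l for _, l in _GENE_PARTS)
        chrom, start, end = placer.place(gene_len)
        parent = FeatureInterval(gid, chrom, start, end, "+", "mRNA", "none")
        features.append(parent)
        hosts.setdefault("mRNA", parent)
        off = start
        for pi, (part, plen) in enumerate(_GENE_PARTS):
            features.append(FeatureInterval(f"{gid}.{part}{pi}", chrom, off, off + plen,
                                            "+", "mRNA", part, parent=gid))
            gene_parts.append((features[-1], part))
            off += plen
    ref.features = features
    for i in range(n_frag):
        want = part_cycle[i % 4]
        cands = [fp_ for fp_ in gene_parts if fp_[1] == want]
        part_feat = cands[i % len(cands)][0]
        length = frag_lengths[i % len(frag_lengths)]
        offset = int(rng.integers(0, part_feat.length - length + 1))
        seq = ref.fetch(part_feat.chrom, part_feat.start + offset,
                        part_feat.start + offset + length, part_feat.strand)
        # species is attributed to the parent gene; sub-feature category comes
        # from mapping, not from the truth table
        species.append(RnaSpecies(f"sp_mRNA_{i}", part_feat.parent, "mRNA", length, False,
                                  (0.08, 0.40, 0.52), "full", frag_w, seq))

    # circular RNAs: circle loci plus short linear windows shed from them
    circ_total_w = 0.010
    for i in range(6):
        circ_len = 160 + 20 * i
        f = _locus(placer, features, f"circ_{i}", "circRNA", circ_len, rng, strand="+")
        hosts.setdefault("circRNA", f)
        ref.features = features
        length = 28 + i
        offset = int(rng.integers(0, circ_len - length))
        species.append(_species_for(f, ref, f"sp_circ_{i}", (0.05, 0.45, 0.50),
                                    circ_total_w / 6, "full", None, circular=True,
                                    length=length, offset=offset))
    _check_circle_junctions(ref, ref.circles)

    # tiny RNAs (10-17 nt) nested inside one host locus of every category
    for cat in CATEGORIES:
        host = hosts[cat]
        for length, w_len in TYRNA_LENGTH_WEIGHTS.items():
            offset = length - 10  # distinct window per length
            if host.length < offset + length:
                offset = 0
            species.append(_species_for(host, ref, f"ty_{cat}_{length}", _TYRNA_FRACS,
                                        w_len / len(CATEGORIES), "full",
                                        length=length, offset=offset))

    ref.validate()
    return ref, species


# ---------------------------------------------------------------------------
# fig4 / fig4-tas presets: planted differential-accumulation clades
# ---------------------------------------------------------------------------

# (n, fracs, planted localization) — survival under (C, R, TR) follows from the
# fractions: full protection everywhere, so surv = (1, in+prot, in). Clades are
# heterogeneous (two protected and two unprotected sub-clades) and fractions
# are balanced so that in every treatment column the non-differential class
# straddles the median of ratios, keeping size factors anchored on it.
_FIG4_CLADES = [
    (7, (0.20, 0.00, 0.80), "inside_EV"),
    (7, (0.25, 0.75, 0.00), "inside_and_outside_protected"),
    (3, (0.60, 0.40, 0.00), "inside_and_outside_protected"),
    (14, (0.022, 0.978, 0.00), "outside_protected"),
    (10, (0.004, 0.996, 0.00), "outside_protected"),
    (14, (0.025, 0.000, 0.975), "outside_unprotected"),
    (7, (0.004, 0.026, 0.970), "outside_unprotected"),
    (32, (0.05, 0.15, 0.80), "ambiguous"),
]
_FIG4_N_TOTAL = 427
_LOW_WEIGHT = 1e-7  # below the detection filter at any realistic depth

_FIG4TAS_CLADES = [
    (16, (0.01, 0.99, 0.00), "outside_protected"),
    (11, (0.02, 0.00, 0.98), "outside_unprotected"),
]
_FIG4TAS_N_TOTAL = 1581


def _planted_preset(config, name, category, clades, n_total):
    rng = child_rng(config.seed, "reference", name)
    genome = _random_genome(rng, 5, 50_000)
    placer = _Placer(genome, rng)
    features: list[FeatureInterval] = []
    ref = Reference(genome, [])
    species: list[RnaSpecies] = []
    n_planted = sum(n for n, _, _ in clades)
    rows = [(fracs, planted, 1.0) for n, fracs, planted in clades for _ in range(n)]
    rows += [((0.05, 0.35, 0.60), "ambiguous", _LOW_WEIGHT)] * (n_total - n_planted)
    for i, (fracs, planted, w) in enumerate(rows):
        fid = f"{category}_{i:04d}"
        f = _locus(placer, features, fid, category, 21, rng)
        ref.features = features
        species.append(_species_for(f, ref, f"sp_{fid}", fracs, w, "full", planted=planted))
    ref.validate()
    return ref, species


def build_fig4(config: GeneratorConfig):
    return _planted_preset(config, "fig4", "miRNA", _FIG4_CLADES, _FIG4_N_TOTAL)


def build_fig4_tas(config: GeneratorConfig):
    return _planted_preset(config, "fig4-tas", "TAS", _FIG4TAS_CLADES, _FIG4TAS_N_TOTAL)


# ---------------------------------------------------------------------------
# rnaser preset
# ---------------------------------------------------------------------------

_RNASER_CIRCLE_LENGTHS = [60, 64, 66, 68, 72, 76]
_RNASER_CIRC_WEIGHT = 0.60
_RNASER_LINEAR_WEIGHT = 0.40
_RNASER_N_LINEAR = 20
_RNASER_LINEAR_LEN = 120


def build_rnaser(config: GeneratorConfig):
    rng = child_rng(config.seed, "reference", "rnaser")
    genome = _random_genome(rng, 2, 30_000)
    placer = _Placer(genome, rng)
    features: list[FeatureInterval] = []
    ref = Reference(genome, [])
    species: list[RnaSpecies] = []

    for i, clen in enumerate(_RNASER_CIRCLE_LENGTHS):
        f = _locus(placer, features, f"circ_{i}", "circRNA", clen, rng, strand="+")
        ref.features = features
        species.append(_species_for(f, ref, f"sp_circ_{i}", (0.0, 0.5, 0.5),
                                    _RNASER_CIRC_WEIGHT / len(_RNASER_CIRCLE_LENGTHS),
                                    "full", circular=True))
    _check_circle_junctions(ref, ref.circles)

    lin_cats = ["rRNA", "mRNA", "TE", "tRNA"]
    for i in range(_RNASER_N_LINEAR):
        cat = lin_cats[i % len(lin_cats)]
        f = _locus(placer, features, f"{cat}_lin_{i}", cat, _RNASER_LINEAR_LEN, rng)
        ref.features = features
        species.append(_species_for(f, ref, f"sp_lin_{i}", (0.10, 0.40, 0.50),
                                    _RNASER_LINEAR_WEIGHT / _RNASER_N_LINEAR, "full"))
    ref.validate()
    return ref, species


PRESETS = {
    "default": build_default,
    "fig4": build_fig4,
    "fig4-tas": build_fig4_tas,
    "rnaser": build_rnaser,
}
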