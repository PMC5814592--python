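"""Synthetic data generators with known ground truth.

Three generators emulate the study design of a wheat-SNP-array analysis of
an *Agropyron* (P genome) outcrossing F1 population and its wheat
derivative lines:

* :func:`simulate_cp_cross` — a 7-chromosome diploid cross-pollinated (CP)
  F1 population: two heterozygous parents, meioses with a Poisson
  crossover process (no interference), segregation patterns hkxhk /
  lmxll / nnxnp, optional transmission distortion, genotyping error and
  missingness.
* :func:`simulate_hit_table` — marker-to-wheat alignment hits with
  collinear positions, a configurable 4P-to-group-2-style rearrangement
  and small-fragment noise.
* :func:`simulate_introgression_lines` — wheat-background (21 chromosome)
  genotypes of alien addition/substitution lines: elevated heterozygous
  calls on the three wheat homoeologs of each added P chromosome and
  elevated missingness on each substituted wheat chromosome.

Every generator is driven by a single integer seed and is byte-identical
across runs for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    AA, AB, BB, NC,
    GenotypeMatrix,
    P_CHROMOSOMES,
    PATTERNS,
    WHEAT_CHROMOSOMES,
    WHEAT_SUBGENOMES,
)

__all__ = [
    "SimChromosome",
    "SimMarker",
    "SimMapTruth",
    "SimCrossConfig",
    "SimLineSpec",
    "Rearrangement",
    "default_map_truth",
    "default_wheat_marker_map",
    "reference_panel_specs",
    "simulate_cp_cross",
    "simulate_hit_table",
    "simulate_introgression_lines",
    "DEFAULT_CHROMOSOME_LENGTHS_CM",
    "DEFAULT_PATTERN_MIX",
]

#: Default linkage-group lengths (cM) for 1P..7P.  The total (839.7 cM),
#: the shortest (87.0, 2P) and the longest (156.7, 3P) follow the map this
#: generator emulates; the remaining lengths sit around its 120 cM mean.
DEFAULT_CHROMOSOME_LENGTHS_CM = (120.0, 87.0, 156.7, 110.0, 125.0, 130.0, 111.0)

#: Default segregation-pattern mix (hkxhk, lmxll, nnxnp), echoing the
#: 735/390/419 marker split of the emulated study.
DEFAULT_PATTERN_MIX = (0.45, 0.27, 0.28)


@dataclass(frozen=True)
class SimChromosome:
    name: str
    length_cM: float


@dataclass(frozen=True)
class SimMarker:
    id: str
    chromosome: str
    true_cM: float
    pattern: str  # hkxhk / lmxll / nnxnp
    distorted: bool = False


@dataclass
class SimMapTruth:
    """True map underlying a simulated CP cross."""

    chromosomes: list
    markers: list

    def __post_init__(self):
        lengths = {c.name: c.length_cM for c in self.chromosomes}
        if len(lengths) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for c in self.chromosomes:
            if c.length_cM < 0:
                raise ValueError(f"negative chromosome length: {c.name}")
        ids = [m.id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("marker ids are not unique")
        per_chrom_patterns = {}
        for m in self.markers:
            if m.chromosome not in lengths:
                raise ValueError(f"marker {m.id} on unknown chromosome {m.chromosome}")
            if not 0 <= m.true_cM <= lengths[m.chromosome]:
                raise ValueError(f"marker {m.id} outside [0, length]")
            if m.pattern not in PATTERNS:
                raise ValueError(f"marker {m.id} has unknown pattern {m.pattern}")
            per_chrom_patterns.setdefault(m.chromosome, set()).add(m.pattern)
        for chrom, pats in per_chrom_patterns.items():
            if len(pats) < 2:
                raise ValueError(
                    f"chromosome {chrom} carries a single segregation pattern; "
                    "male and female maps both need informative markers"
                )

    def markers_on(self, chrom: str) -> list:
        sub = [m for m in self.markers if m.chromosome == chrom]
        return sorted(sub, key=lambda m: (m.true_cM, m.id))


@dataclass
class SimCrossConfig:
    """Study-design knobs of the simulated CP cross.

    Defaults are the emulated study's conditions: 119 F1 progeny, 1%
    genotyping error, 15% missing calls, no transmission distortion.
    """

    n_progeny: int = 119
    genotyping_error_rate: float = 0.01
    missing_rate: float = 0.15
    distorted_fraction: float = 0.0
    distortion_strength: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("genotyping_error_rate", "missing_rate", "distorted_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.n_progeny < 2:
            raise ValueError("n_progeny must be at least 2")
        if not 0 <= self.distortion_strength < 0.5:
            raise ValueError("distortion_strength must lie in [0, 0.5)")


def default_map_truth(
    n_markers_per_chromosome: int = 100,
    lengths_cM=DEFAULT_CHROMOSOME_LENGTHS_CM,
    pattern_mix=DEFAULT_PATTERN_MIX,
    distorted_fraction: float = 0.0,
    seed: int = 0,
) -> SimMapTruth:
    """Seven P chromosomes with uniformly scattered markers.

    Pattern labels are dealt out in fixed proportions and shuffled per
    chromosome; ``distorted_fraction`` of markers are flagged for skewed
    transmission.
    """
    rng = np.random.default_rng(seed)
    chroms = [SimChromosome(name, float(L)) for name, L in zip(P_CHROMOSOMES, lengths_cM)]
    markers = []
    for chrom in chroms:
        pos = np.sort(rng.uniform(0.0, chrom.length_cM, n_markers_per_chromosome))
        counts = np.floor(np.asarray(pattern_mix) * n_markers_per_chromosome).astype(int)
        counts[0] += n_markers_per_chromosome - counts.sum()
        labels = np.repeat(np.arange(3), counts)
        rng.shuffle(labels)
        distorted = rng.random(n_markers_per_chromosome) < distorted_fraction
        for i in range(n_markers_per_chromosome):
            markers.append(
                SimMarker(
                    id=f"{chrom.name}_m{i:04d}",
                    chromosome=chrom.name,
                    true_cM=float(pos[i]),
                    pattern=PATTERNS[labels[i]],
                    distorted=bool(distorted[i]),
                )
            )
    return SimMapTruth(chroms, markers)


def _meiosis_haplotypes(rng, length_cM, positions_cM, n_gametes):
    """Haplotype origin (0/1) of each gamete at each marker position.

    Crossover count per meiosis is Poisson(length/100); crossover
    positions are uniform on the chromosome (no interference).
    """
    n_mark = len(positions_cM)
    origin = np.empty((n_mark, n_gametes), dtype=np.int8)
    breakpoints = []
    start = rng.integers(0, 2, size=n_gametes)
    n_xo = rng.poisson(length_cM / 100.0, size=n_gametes)
    for g in range(n_gametes):
        xo = np.sort(rng.uniform(0.0, length_cM, size=n_xo[g])) if n_xo[g] else np.empty(0)
        crossings = np.searchsorted(xo, positions_cM, side="right")
        origin[:, g] = (start[g] + crossings) % 2
        breakpoints.append(xo)
    return origin, breakpoints


def simulate_cp_cross(truth: SimMapTruth, cfg: SimCrossConfig):
    """Simulate genotypes of a CP F1 population.

    Returns ``(gm, sim_truth)`` where ``gm`` is a
    :class:`~agmap.datatypes.GenotypeMatrix` holding father, mother and
    progeny calls and ``sim_truth`` is a dict with the phased parental
    alleles, per-progeny haplotype origins and crossover breakpoints.

    Parent calls follow each marker's pattern exactly (hkxhk: both AB;
    lmxll: father AB, mother AA; nnxnp: father AA, mother AB); progeny
    calls are the product of one simulated paternal and one maternal
    meiosis per chromosome, then genotyping error (a call is replaced by
    one of the two other calls, equiprobably) and missingness are applied
    independently.  Markers flagged ``distorted`` skew each heterozygous
    parent's transmitted allele towards the B allele by
    ``distortion_strength``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_progeny
    marker_order = [m.id for m in truth.markers]
    n_mark = len(marker_order)
    calls = np.full((n_mark, n + 2), NC, dtype=np.int8)
    pat_origin = np.full((n_mark, n), -1, dtype=np.int8)
    mat_origin = np.full((n_mark, n), -1, dtype=np.int8)
    father_hap0 = np.full(n_mark, -1, dtype=np.int8)
    mother_hap0 = np.full(n_mark, -1, dtype=np.int8)
    breakpoints = {}
    row_of = {mid: i for i, mid in enumerate(marker_order)}

    for chrom in truth.chromosomes:
        markers = truth.markers_on(chrom.name)
        if not markers:
            continue
        pos = np.array([m.true_cM for m in markers])
        rows = np.array([row_of[m.id] for m in markers])
        het_f = np.array([m.pattern in ("hkxhk", "lmxll") for m in markers])
        het_m = np.array([m.pattern in ("hkxhk", "nnxnp") for m in markers])
        distorted = np.array([m.distorted for m in markers])

        # random phase: allele carried by haplotype 0 at heterozygous markers
        f_h0 = np.where(het_f, rng.integers(0, 2, len(markers)), 0).astype(np.int8)
        m_h0 = np.where(het_m, rng.integers(0, 2, len(markers)), 0).astype(np.int8)
        father_hap0[rows] = np.where(het_f, f_h0, -1)
        mother_hap0[rows] = np.where(het_m, m_h0, -1)

        orig_f, bp_f = _meiosis_haplotypes(rng, chrom.length_cM, pos, n)
        orig_m, bp_m = _meiosis_haplotypes(rng, chrom.length_cM, pos, n)
        breakpoints[chrom.name] = {"paternal": bp_f, "maternal": bp_m}

        # transmitted allele: haplotype 0 carries f_h0, haplotype 1 its complement
        allele_f = np.where(orig_f == 0, f_h0[:, None], 1 - f_h0[:, None])
        allele_f = np.where(het_f[:, None], allele_f, 0)
        allele_m = np.where(orig_m == 0, m_h0[:, None], 1 - m_h0[:, None])
        allele_m = np.where(het_m[:, None], allele_m, 0)

        if distorted.any() and cfg.distortion_strength > 0:
            p = 0.5 + cfg.distortion_strength
            skew_mask = distorted[:, None]
            redraw_f = (rng.random((len(markers), n)) < p).astype(np.int8)
            allele_f = np.where(skew_mask & het_f[:, None], redraw_f, allele_f)
            redraw_m = (rng.random((len(markers), n)) < p).astype(np.int8)
            allele_m = np.where(skew_mask & het_m[:, None], redraw_m, allele_m)

        geno = (allele_f + allele_m).astype(np.int8)
        calls[rows, 2:] = geno
        pat_origin[rows, :] = orig_f
        mat_origin[rows, :] = orig_m
        # parent calls
        calls[rows, 0] = np.where(het_f, AB, AA)
        calls[rows, 1] = np.where(het_m, AB, AA)

    # genotyping error on progeny calls: uniformly one of the other two calls
    if cfg.genotyping_error_rate > 0:
        err = rng.random((n_mark, n)) < cfg.genotyping_error_rate
        shift = rng.integers(1, 3, size=(n_mark, n))
        calls[:, 2:] = np.where(err, (calls[:, 2:] + shift) % 3, calls[:, 2:]).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random((n_mark, n)) < cfg.missing_rate
        calls[:, 2:] = np.where(miss, NC, calls[:, 2:]).astype(np.int8)

    sample_ids = ["father", "mother"] + [f"F1_{i + 1:03d}" for i in range(n)]
    roles = ["father", "mother"] + ["progeny"] * n
    gm = GenotypeMatrix(calls, pd.Index(marker_order), pd.Index(sample_ids), roles)
    sim_truth = {
        "father_hap0_allele": pd.Series(father_hap0, index=marker_order),
        "mother_hap0_allele": pd.Series(mother_hap0, index=marker_order),
        "paternal_origin": pd.DataFrame(pat_origin, index=marker_order, columns=sample_ids[2:]),
        "maternal_origin": pd.DataFrame(mat_origin, index=marker_order, columns=sample_ids[2:]),
        "breakpoints": breakpoints,
        "marker_chromosome": pd.Series(
            {m.id: m.chromosome for m in truth.markers}, name="chromosome"
        ),
        "marker_cM": pd.Series({m.id: m.true_cM for m in truth.markers}, name="true_cM"),
    }
    return gm, sim_truth


# ---------------------------------------------------------------------------
# Alignment-hit tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rearrangement:
    """A segment of a P chromosome whose markers hit an alternate group."""

    chromosome: str
    start_cM: float
    end_cM: float
    target_group: int


def default_rearrangements(truth: SimMapTruth, fraction: float = 0.4):
    """The default 4P-style event: the proximal ``fraction`` of 4P hits group 2."""
    for c in truth.chromosomes:
        if c.name == "4P":
            return [Rearrangement("4P", 0.0, fraction * c.length_cM, 2)]
    return []


def simulate_hit_table(
    truth: SimMapTruth,
    scheme: dict | None = None,
    rearrangements: list | None = None,
    noise_rate: float = 0.02,
    seed: int = 0,
    chromosome_length_bp: float = 600e6,
    secondary_hit_rate: float = 0.5,
    junk_hit_rate: float = 0.1,
):
    """Simulate a BLAST-like marker-to-wheat hit table.

    Each marker's top hit falls on a wheat chromosome of its true
    homoeologous group (subgenome A/B/D uniform), at a bp position
    proportional to its cM position so blocks are collinear.  Markers in a
    rearranged segment hit the alternate group near the start of the
    target chromosome; ``noise_rate`` markers hit a uniformly random wheat
    chromosome at a random position.  Secondary same-group hits and junk
    hits above the e-value cutoff are added to exercise filtering.

    Returns ``(hits, hit_truth)`` DataFrames.
    """
    if scheme is None:
        scheme = {f"{g}P": g for g in range(1, 8)}
    groups = sorted(set(scheme.values()))
    if sorted(scheme.keys()) != sorted(c.name for c in truth.chromosomes) or groups != list(
        range(1, 8)
    ):
        raise ValueError("scheme must map the truth's P chromosomes onto groups 1..7")
    if rearrangements is None:
        rearrangements = default_rearrangements(truth)
    by_chrom = {}
    for re_ in rearrangements:
        if re_.end_cM <= re_.start_cM:
            raise ValueError("rearrangement segment must have positive span")
        for other in by_chrom.get(re_.chromosome, []):
            if re_.start_cM < other.end_cM and other.start_cM < re_.end_cM:
                raise ValueError("overlapping rearrangement segments")
        by_chrom.setdefault(re_.chromosome, []).append(re_)

    rng = np.random.default_rng(seed)
    lengths = {c.name: c.length_cM for c in truth.chromosomes}
    rows, truth_rows = [], []
    for m in truth.markers:
        L = max(lengths[m.chromosome], 1e-9)
        seg = next(
            (s for s in by_chrom.get(m.chromosome, []) if s.start_cM <= m.true_cM < s.end_cM),
            None,
        )
        is_noise = rng.random() < noise_rate
        subgenome = WHEAT_SUBGENOMES[rng.integers(0, 3)]
        if is_noise:
            chrom = WHEAT_CHROMOSOMES[rng.integers(0, 21)]
            bp = int(rng.uniform(0, chromosome_length_bp))
        elif seg is not None:
            chrom = f"{seg.target_group}{subgenome}"
            frac = (m.true_cM - seg.start_cM) / (seg.end_cM - seg.start_cM)
            bp = int(frac * 0.35 * chromosome_length_bp) + 1
        else:
            chrom = f"{scheme[m.chromosome]}{subgenome}"
            bp = int(m.true_cM / L * 0.98 * chromosome_length_bp) + 1
        e_top = 10.0 ** (-rng.uniform(8.0, 30.0))
        rows.append((m.id, chrom, bp, e_top, float(rng.uniform(0.92, 1.0))))
        if rng.random() < secondary_hit_rate:
            other = rng.permutation([s for s in WHEAT_SUBGENOMES if s != chrom[-1]])[0]
            rows.append(
                (
                    m.id,
                    f"{chrom[0]}{other}",
                    max(1, bp + int(rng.normal(0, 2e6))),
                    e_top * 10 ** rng.uniform(1.0, 4.0),
                    float(rng.uniform(0.88, 0.99)),
                )
            )
        if rng.random() < junk_hit_rate:
            rows.append(
                (
                    m.id,
                    WHEAT_CHROMOSOMES[rng.integers(0, 21)],
                    int(rng.uniform(0, chromosome_length_bp)),
                    10.0 ** (-rng.uniform(0.5, 4.5)),
                    float(rng.uniform(0.7, 0.9)),
                )
            )
        truth_rows.append(
            {
                "marker_id": m.id,
                "chromosome": m.chromosome,
                "true_group": scheme[m.chromosome],
                "hit_group": int(chrom[0]),
                "rearranged": seg is not None and not is_noise,
                "noise": bool(is_noise),
            }
        )
    hits = pd.DataFrame(
        rows, columns=["marker_id", "wheat_chromosome", "bp_position", "e_value", "identity"]
    )
    return hits, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Wheat-background introgression lines
# ---------------------------------------------------------------------------

@dataclass
class SimLineSpec:
    """Composition and signal strengths of one derivative line.

    ``additions`` lists the P chromosomes present in the line (including
    the P partner of any substitution); ``substitutions`` pairs each
    replaced wheat chromosome with its homoeologous P chromosome.  Added P
    chromosomes raise heterozygous-call rates on their three wheat
    homoeologs (array probes cross-hybridise); a substituted wheat
    chromosome raises missingness because its own copies are gone.
    """

    line_id: str
    additions: frozenset = frozenset()
    substitutions: frozenset = frozenset()  # of (P chromosome, wheat chromosome)
    baseline_het: float = 0.01
    homoeolog_het: float = 0.15
    baseline_missing: float = 0.05
    substituted_missing: float = 0.6

    def __post_init__(self):
        self.additions = frozenset(self.additions)
        self.substitutions = frozenset(self.substitutions)
        if self.homoeolog_het <= self.baseline_het:
            raise ValueError("homoeolog_het must exceed baseline_het")
        if self.substituted_missing <= self.baseline_missing:
            raise ValueError("substituted_missing must exceed baseline_missing")

    @property
    def composition(self) -> str:
        n_w = 42 - 2 * len(self.substitutions)
        n_p = 2 * len(self.additions)
        return f"{n_w}W + {n_p}P"

    @property
    def expected_alien_count(self) -> int:
        """Number of alien chromosome pairs (as a GISH count would give)."""
        return len(self.additions)


def default_wheat_marker_map(
    n_per_chromosome: int = 300,
    chromosome_length_bp: float = 600e6,
    genome_specific_fraction: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Evenly spaced wheat markers over 21 chromosomes of equal length.

    A ``genome_specific`` subset (default 30%) marks probes that only
    hybridise to their own subgenome; the substitution caller computes
    missing rates on that subset.
    """
    rng = np.random.default_rng(seed)
    rows = []
    spacing = chromosome_length_bp / n_per_chromosome
    for chrom in WHEAT_CHROMOSOMES:
        specific = rng.random(n_per_chromosome) < genome_specific_fraction
        for i in range(n_per_chromosome):
            rows.append(
                {
                    "marker_id": f"{chrom}_w{i:04d}",
                    "chromosome": chrom,
                    "bp_position": int((i + 0.5) * spacing),
                    "genome_specific": bool(specific[i]),
                }
            )
    return pd.DataFrame(rows)


def _homoeologs(p_chrom: str, scheme: dict) -> list:
    group = scheme[p_chrom]
    return [f"{group}{s}" for s in WHEAT_SUBGENOMES]


def simulate_introgression_lines(
    specs: list,
    wheat_marker_map: pd.DataFrame | None = None,
    scheme: dict | None = None,
    seed: int = 0,
):
    """Simulate line genotypes on the wheat background.

    Returns ``(gm, truth)`` where ``gm`` holds one column per line (role
    ``line``) over the wheat marker map and ``truth`` is a per-line
    DataFrame of the generating additions/substitutions.
    """
    if scheme is None:
        scheme = {f"{g}P": g for g in range(1, 8)}
    if wheat_marker_map is None:
        wheat_marker_map = default_wheat_marker_map(seed=seed)
    chroms = wheat_marker_map["chromosome"].to_numpy()
    known = set(WHEAT_CHROMOSOMES)
    rng = np.random.default_rng(seed)
    n_mark = len(wheat_marker_map)
    calls = np.empty((n_mark, len(specs)), dtype=np.int8)
    truth_rows = []
    for j, spec in enumerate(specs):
        for p in spec.additions:
            if p not in scheme:
                raise ValueError(f"{spec.line_id}: unknown P chromosome {p}")
        for p, w in spec.substitutions:
            if p not in scheme or w not in known:
                raise ValueError(f"{spec.line_id}: unknown chromosome in substitution {(p, w)}")
            if int(w[0]) != scheme[p]:
                raise ValueError(
                    f"{spec.line_id}: substituted {w} is not homoeologous to {p}"
                )
        hot = set()
        for p in spec.additions:
            hot.update(_homoeologs(p, scheme))
        substituted = {w for _, w in spec.substitutions}
        p_het = np.where(np.isin(chroms, sorted(hot)), spec.homoeolog_het, spec.baseline_het)
        p_nc = np.where(
            np.isin(chroms, sorted(substituted)), spec.substituted_missing, spec.baseline_missing
        )
        g = np.where(rng.random(n_mark) < p_het, AB, AA).astype(np.int8)
        g = np.where(rng.random(n_mark) < p_nc, NC, g).astype(np.int8)
        calls[:, j] = g
        truth_rows.append(
            {
                "line_id": spec.line_id,
                "composition": spec.composition,
                "additions": "+".join(sorted(spec.additions)),
                "substitutions": "+".join(
                    f"{p}/{w}" for p, w in sorted(spec.substitutions)
                ),
                "expected_alien_count": spec.expected_alien_count,
            }
        )
    gm = GenotypeMatrix(
        calls,
        pd.Index(wheat_marker_map["marker_id"]),
        pd.Index([s.line_id for s in specs]),
        ["line"] * len(specs),
    )
    return gm, pd.DataFrame(truth_rows)


# Published compositions of the 35 wheat-A. cristatum derivative lines used
# as the reference panel: (accession, additions, substitutions).
_PANEL = [
    ("10521-2", ("1P",), ()),
    ("II-3-1A-1", ("1P", "2P"), ()),
    ("II-3-1", ("1P", "2P"), (("1P", "1A"),)),
    ("II-4", ("1P", "2P"), ()),
    ("2-57-1", ("2P",), ()),
    ("2-72", ("2P",), ()),
    ("II-29-1", ("2P",), ()),
    ("II-9-3", ("2P",), ()),
    ("II-8-1", ("2P",), ()),
    ("II-7-1", ("2P",), ()),
    ("7365", ("3P",), (("3P", "3B"),)),
    ("4-11", ("4P",), ()),
    ("4-12", ("4P",), ()),
    ("4-6", ("4P",), ()),
    ("4-7", ("4P",), ()),
    ("4-8", ("4P",), ()),
    ("II-21-2", ("4P",), ()),
    ("II-21-6", ("4P",), ()),
    ("35524", ("5P",), ()),
    ("II-11-1", ("2P", "5P"), ()),
    ("5113-2", ("6P",), ()),
    ("5114-3", ("6P",), ()),
    ("II-30-5", ("6P",), ()),
    ("4844-12", ("6P",), ()),
    ("4844-8", ("6P",), (("6P", "6D"),)),
    ("II-1-1", ("7P",), ()),
    ("7-49", ("7P",), ()),
    ("7-64", ("7P",), (("7P", "7D"),)),
    ("7-65", ("7P",), (("7P", "7D"),)),
    ("7-7", ("7P",), (("7P", "7A"),)),
    ("5038", ("7P",), ()),
    ("5043", ("7P",), ()),
    ("II-1-3", ("7P",), ()),
    ("II-5-1", ("7P",), ()),
    ("II-26-1", ("7P",), ()),
]


def reference_panel_specs(**signal_kwargs) -> list:
    """The 35-line reference panel as :class:`SimLineSpec` objects.

    26 single disomic additions, 3 double additions, 5 substitutions and
    one combined addition+substitution line; signal strengths can be
    overridden via keyword arguments.
    """
    return [
        SimLineSpec(line_id, frozenset(add), frozenset(sub), **signal_kwargs)
        for line_id, add, sub in _PANEL
    ]
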