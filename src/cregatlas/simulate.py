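"""Synthetic four-species data with planted truth.

Every pipeline input — genomes with chain maps, gap and repeat tracks,
per-replicate peak calls, a raw count matrix, four-way alignment
columns, cell-type/disease annotation sets and a 4C fragment profile —
is generated from one :class:`SimulationConfig` and one integer seed,
with a truth table recording each region's planted class, cell type and
per-species mean enrichment.  Default parameters describe the study
conditions the downstream statistics assume: four species, two brain
tissues, three replicates of moderately overdispersed counts
(NB variance mu + 0.05 mu^2) over ~2 kb regions, a four-fold planted
hominin effect, and small fractions of unmappable and repeat-confounded
regions.

Each generator draws from a named child stream of the root seed, so the
outputs of one generator never depend on whether another ran.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from cregatlas._rng import child_rng
from cregatlas.chains import Chain, ChainMap
from cregatlas.intervals import GenomicInterval, PeakSet
from cregatlas.fourc import FragmentProfile
from cregatlas.seqscores import AlignmentColumns

__all__ = [
    "SimulationConfig",
    "GenomeBundle",
    "SimulatedBundle",
    "make_truth",
    "simulate_genomes",
    "simulate_peaks",
    "simulate_counts",
    "simulate_alignments",
    "simulate_annotation_sets",
    "simulate_fourc",
    "simulate_bundle",
    "make_design",
]

TRUTH_CLASSES = (
    "stable",
    "hominin_gain",
    "hominin_loss",
    "human_gain",
    "chimp_gain",
    "repeat_confounded",
    "unmappable",
)

CELL_TYPES = ("oligodendrocyte", "astrocyte", "neuron", "microglia")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    n_regions: int = 2000
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    species: tuple[str, ...] = ("human", "chimp", "macaque", "marmoset")
    tissues: tuple[str, ...] = ("CB", "PFC")
    replicates_per_group: int = 3
    nb_dispersion: float = 0.05
    baseline_mean: float = 100.0
    planted_gain_fraction: float = 0.05
    planted_loss_fraction: float = 0.05
    planted_log2fc: float = 2.0
    human_gain_fraction: float = 0.0
    chimp_gain_fraction: float = 0.0
    oligo_fraction_in_gains: float = 0.6
    oligo_fraction_background: float = 0.1
    asd_down_fraction_in_gains: float = 0.3
    asd_down_fraction_background: float = 0.05
    hominin_substitution_rate_gain: float = 0.02
    hominin_substitution_rate_background: float = 0.005
    indel_rate: float = 1e-5
    repeat_fraction: float = 0.05
    unmappable_fraction: float = 0.05
    gap_fraction: float = 0.05
    fourc_n_fragments: int = 2001
    fourc_decay_bp: float = 200_000.0
    fourc_peak_mean: float = 500.0
    seed: int = 0

    def validate(self) -> list[str]:
        """Return human-readable violations; empty when the config is usable."""
        v = []
        props = [
            "planted_gain_fraction",
            "planted_loss_fraction",
            "human_gain_fraction",
            "chimp_gain_fraction",
            "oligo_fraction_in_gains",
            "oligo_fraction_background",
            "asd_down_fraction_in_gains",
            "asd_down_fraction_background",
            "hominin_substitution_rate_gain",
            "hominin_substitution_rate_background",
            "repeat_fraction",
            "unmappable_fraction",
            "gap_fraction",
            "indel_rate",
        ]
        for name in props:
            x = getattr(self, name)
            if not (0.0 <= x <= 1.0):
                v.append(f"{name}={x} outside [0, 1]")
        planted = (
            self.planted_gain_fraction
            + self.planted_loss_fraction
            + self.human_gain_fraction
            + self.chimp_gain_fraction
            + self.repeat_fraction
            + self.unmappable_fraction
        )
        if planted > 1.0:
            v.append(f"planted class fractions sum to {planted} > 1")
        if self.nb_dispersion < 0:
            v.append("nb_dispersion must be >= 0")
        if len(self.species) != 4:
            v.append("exactly 4 species labels required")
        if self.replicates_per_group < 2:
            v.append("need at least 2 replicates per group")
        if self.n_regions < 1 or self.n_chroms < 1 or self.chrom_length < 1:
            v.append("n_regions, n_chroms and chrom_length must be positive")
        return v

    @property
    def reference(self) -> str:
        return self.species[0]


@dataclass
class GenomeBundle:
    """Per-species genome skeletons plus the chain maps to the reference."""

    reference: str
    chrom_sizes: dict[str, dict[str, int]]  # species -> chrom -> length
    gap_tracks: dict[str, list[GenomicInterval]]
    repeat_tracks: dict[str, list[GenomicInterval]]
    chains: dict[tuple[str, str], ChainMap]  # (src, tgt) both directions
    region_coords: dict[str, dict[str, GenomicInterval]]  # species -> region_id -> iv


def _require_valid(config: SimulationConfig) -> None:
    problems = config.validate()
    if problems:
        raise ValueError("invalid SimulationConfig: " + "; ".join(problems))


def make_truth(config: SimulationConfig) -> pd.DataFrame:
    """Place regions on the reference genome and assign planted classes."""
    _require_valid(config)
    rng = child_rng(config.seed, "truth")
    n, n_chroms = config.n_regions, config.n_chroms
    per_chrom = [n // n_chroms + (1 if k < n % n_chroms else 0) for k in range(n_chroms)]
    rows = []
    rid = 0
    for ck, n_here in enumerate(per_chrom):
        if n_here == 0:
            continue
        spacing = config.chrom_length // (n_here + 1)
        widths = np.clip(rng.normal(2000, 200, n_here), 900, 3600).astype(int)
        if spacing < widths.max() + 1000:
            raise ValueError(
                f"chrom_length {config.chrom_length} too small to place "
                f"{n_here} non-overlapping regions"
            )
        jitter = rng.integers(-spacing // 8, spacing // 8 + 1, n_here)
        for i in range(n_here):
            center = (i + 1) * spacing + int(jitter[i])
            start = max(100, center - int(widths[i]) // 2)
            rows.append((f"T{rid:05d}", f"chr{ck + 1}", start, start + int(widths[i])))
            rid += 1
    truth = pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end"])

    probs = np.array(
        [
            config.unmappable_fraction,
            config.repeat_fraction,
            config.planted_gain_fraction,
            config.planted_loss_fraction,
            config.human_gain_fraction,
            config.chimp_gain_fraction,
        ]
    )
    labels = [
        "unmappable",
        "repeat_confounded",
        "hominin_gain",
        "hominin_loss",
        "human_gain",
        "chimp_gain",
    ]
    u = rng.random(n)
    edges = np.concatenate([[0.0], np.cumsum(probs)])
    cls = np.full(n, "stable", dtype=object)
    for k, lab in enumerate(labels):
        cls[(u >= edges[k]) & (u < edges[k + 1])] = lab
    truth["true_class"] = cls

    base = config.baseline_mean * rng.lognormal(0.0, 0.5, n)
    fc = 2.0**config.planted_log2fc
    hu, ch, rm, mm = config.species
    means = {sp: base.copy() for sp in config.species}
    means[hu][cls == "hominin_gain"] *= fc
    means[ch][cls == "hominin_gain"] *= fc
    means[hu][cls == "hominin_loss"] /= fc
    means[ch][cls == "hominin_loss"] /= fc
    means[hu][cls == "human_gain"] *= fc
    means[ch][cls == "chimp_gain"] *= fc
    for sp in config.species:
        truth[f"mean_{sp}"] = means[sp]

    is_gain = cls == "hominin_gain"
    cell = np.full(n, "", dtype=object)
    r = rng.random(n)
    cell[is_gain & (r < config.oligo_fraction_in_gains)] = "oligodendrocyte"
    bg_oligo = ~is_gain & (r < config.oligo_fraction_background)
    cell[bg_oligo] = "oligodendrocyte"
    # sprinkle the other cell types over the remaining background regions
    r2 = rng.random(n)
    for k, label in enumerate(CELL_TYPES[1:]):
        pick = (
            ~is_gain
            & (cell == "")
            & (r2 >= 0.05 * k)
            & (r2 < 0.05 * (k + 1))
        )
        cell[pick] = label
    truth["true_cell_type"] = cell
    r3 = rng.random(n)
    truth["true_asd_down"] = np.where(
        is_gain,
        r3 < config.asd_down_fraction_in_gains,
        r3 < config.asd_down_fraction_background,
    )
    return truth


# ---------------------------------------------------------------------------
# genomes and chains
# ---------------------------------------------------------------------------


def _build_species_chrom(
    L: int,
    events: list[tuple[int, int, int]],  # (ref_pos, del_ref_len, ins_sp_len)
    chrom: str,
    sp_chrom: str,
) -> tuple[Chain, int]:
    """Chain blocks ref->species for one chromosome given indel events."""
    src_starts, tgt_starts, sizes = [], [], []
    ref_pos, sp_pos = 0, 0
    for pos, dt, dq in sorted(events):
        size = pos - ref_pos
        if size > 0:
            src_starts.append(ref_pos)
            tgt_starts.append(sp_pos)
            sizes.append(size)
            sp_pos += size
        ref_pos = min(pos + dt, L)
        sp_pos += dq
    if L - ref_pos > 0:
        src_starts.append(ref_pos)
        tgt_starts.append(sp_pos)
        sizes.append(L - ref_pos)
        sp_pos += L - ref_pos
    chain = Chain(
        src_chrom=chrom,
        tgt_chrom=sp_chrom,
        src_size=L,
        tgt_size=sp_pos,
        strand="+",
        src_starts=np.array(src_starts, dtype=np.int64),
        tgt_starts=np.array(tgt_starts, dtype=np.int64),
        sizes=np.array(sizes, dtype=np.int64),
    )
    return chain, sp_pos


def _carve_segments(
    rng: np.random.Generator,
    free: list[tuple[int, int]],
    target: int,
    seg_mean: int = 1000,
) -> list[tuple[int, int]]:
    """Cut ~seg_mean-sized segments out of free space until target bases.

    Several segments may land in one free interval (separated by short
    untouched spacers), so the target is met whenever the free space can
    hold it.
    """
    free = [f for f in free if f[1] > f[0]]
    order = rng.permutation(len(free))
    out = []
    remaining = target
    for k in order:
        if remaining <= 0:
            break
        s, e = free[k]
        pos = s + int(rng.integers(0, max(1, min(seg_mean, e - s))))
        while pos < e and remaining > 0:
            seg = int(min(remaining, rng.integers(seg_mean // 2, seg_mean * 2), e - pos))
            if seg <= 0:
                break
            out.append((pos, pos + seg))
            remaining -= seg
            pos += seg + int(rng.integers(50, 500))
    return sorted(out)


def simulate_genomes(
    config: SimulationConfig, truth: pd.DataFrame | None = None
) -> GenomeBundle:
    """Per-species chromosome sizes, gap/repeat tracks and chain maps.

    Planted ``unmappable`` regions are deleted from the chain of one
    non-reference species; ``repeat_confounded`` regions get a repeat
    annotation (and a duplicated locus) in one non-reference species.
    Random small indels at ``indel_rate`` land between regions so they
    perturb alignment block structure without destroying orthology.
    """
    _require_valid(config)
    if truth is None:
        truth = make_truth(config)
    rng = child_rng(config.seed, "genomes")
    ref = config.reference
    others = [sp for sp in config.species if sp != ref]

    unmappable = truth[truth["true_class"] == "unmappable"]
    repeats = truth[truth["true_class"] == "repeat_confounded"]
    unmap_sp = {
        row.region_id: others[int(k)]
        for row, k in zip(
            unmappable.itertuples(index=False),
            rng.integers(0, len(others), len(unmappable)),
        )
    }
    repeat_sp = {
        row.region_id: others[int(k)]
        for row, k in zip(
            repeats.itertuples(index=False),
            rng.integers(0, len(others), len(repeats)),
        )
    }

    chroms = sorted(truth["chrom"].unique(), key=lambda c: int(c[3:]))
    chrom_sizes: dict[str, dict[str, int]] = {ref: {c: config.chrom_length for c in chroms}}
    chains: dict[tuple[str, str], ChainMap] = {}
    region_coords: dict[str, dict[str, GenomicInterval]] = {
        ref: {
            row.region_id: GenomicInterval(
                ref, row.chrom, row.start, row.end, id=row.region_id
            )
            for row in truth.itertuples(index=False)
        }
    }

    occupied = {
        c: sorted(
            (row.start - 200, row.end + 200)
            for row in truth.itertuples(index=False)
            if row.chrom == c
        )
        for c in chroms
    }
    # gaps and duplicated loci keep a wide berth from the regions *in the
    # coordinates of the species that carries them*, so that regions
    # extended to the 2 kb minimum width never brush against them
    def free_space(sp: str, c: str, L: int) -> list[tuple[int, int]]:
        spans = sorted(
            (iv.start - 3000, iv.end + 3000)
            for iv in region_coords[sp].values()
            if iv.chrom == c
        )
        out, prev = [], 0
        for s, e in spans:
            if s > prev:
                out.append((prev, min(s, L)))
            prev = max(prev, e)
        if prev < L:
            out.append((prev, L))
        return out

    for sp in others:
        sp_chains = []
        sp_sizes = {}
        offsets_by_chrom = {}
        for c in chroms:
            L = config.chrom_length
            events: list[tuple[int, int, int]] = []
            for row in truth[truth["chrom"] == c].itertuples(index=False):
                if unmap_sp.get(row.region_id) == sp:
                    events.append((row.start - 50, row.end - row.start + 100, 0))
            n_indels = rng.binomial(L, config.indel_rate)
            pos = np.sort(rng.integers(0, L, n_indels))
            spans = occupied[c]
            starts = np.array([s for s, _ in spans])
            ends = np.array([e for _, e in spans])
            for p in pos:
                k = np.searchsorted(starts, p) - 1
                if k >= 0 and p < ends[k]:
                    continue  # keep indels out of region bodies
                size = int(rng.integers(1, 51))
                if rng.random() < 0.5:
                    events.append((int(p), size, 0))  # deletion in species
                else:
                    events.append((int(p), 0, size))  # insertion in species
            chain, sp_len = _build_species_chrom(L, events, c, c)
            sp_chains.append(chain)
            sp_sizes[c] = sp_len
            ev = sorted(events)
            offsets_by_chrom[c] = (
                np.array([p for p, _, _ in ev], dtype=np.int64),
                np.cumsum([dq - dt for _, dt, dq in ev]).astype(np.int64),
            )
        fwd = ChainMap(ref, sp, sp_chains)
        chains[(ref, sp)] = fwd
        chains[(sp, ref)] = fwd.invert()
        chrom_sizes[sp] = sp_sizes

        coords = {}
        for row in truth.itertuples(index=False):
            if unmap_sp.get(row.region_id) == sp:
                continue
            pos_arr, cum = offsets_by_chrom[row.chrom]
            k = int(np.searchsorted(pos_arr, row.start, side="right"))
            off = int(cum[k - 1]) if k > 0 else 0
            coords[row.region_id] = GenomicInterval(
                sp, row.chrom, row.start + off, row.end + off, id=row.region_id
            )
        region_coords[sp] = coords

    # assembly gaps: a binomially drawn base total per chromosome, carved
    # into ~kb segments of inter-region space
    gap_tracks: dict[str, list[GenomicInterval]] = {}
    for sp in config.species:
        track = []
        for c in chroms:
            L = chrom_sizes[sp][c]
            target = int(rng.binomial(L, config.gap_fraction))
            free = free_space(sp, c, L)
            for s, e in _carve_segments(rng, free, target):
                track.append(GenomicInterval(sp, c, s, e))
        gap_tracks[sp] = sorted(track, key=lambda iv: (iv.chrom, iv.start))

    # repeats: the region's locus in the assigned species plus a duplicate
    # copy elsewhere, so multimap-only enrichment is detectable there
    repeat_tracks: dict[str, list[GenomicInterval]] = {sp: [] for sp in config.species}
    for row in repeats.itertuples(index=False):
        sp = repeat_sp[row.region_id]
        iv = region_coords[sp].get(row.region_id)
        if iv is None:
            continue
        repeat_tracks[sp].append(replace(iv, id=f"{row.region_id}:site"))
        free = free_space(sp, iv.chrom, chrom_sizes[sp][iv.chrom])
        dup = _carve_segments(rng, free, iv.width, seg_mean=iv.width)
        if dup:
            s, e = dup[0]
            repeat_tracks[sp].append(
                GenomicInterval(sp, iv.chrom, s, max(e, s + 1), id=f"{row.region_id}:dup")
            )
    for sp in repeat_tracks:
        repeat_tracks[sp].sort(key=lambda iv: (iv.chrom, iv.start))

    return GenomeBundle(
        reference=ref,
        chrom_sizes=chrom_sizes,
        gap_tracks=gap_tracks,
        repeat_tracks=repeat_tracks,
        chains=chains,
        region_coords=region_coords,
    )


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------


def simulate_peaks(
    config: SimulationConfig,
    truth: pd.DataFrame,
    genomes: GenomeBundle,
) -> tuple[dict[tuple[str, str, str], PeakSet], dict[str, tuple[PeakSet, PeakSet]]]:
    """Per-replicate unique-mapping peak calls plus multimap peak sets.

    Each region yields a jittered peak per species/tissue/replicate
    (occasionally a narrow summit-only call, occasionally dropped).
    Repeat-confounded regions are absent from the unique peaks of their
    repeat species but present — along with their duplicate locus — in
    that species' multimap peaks.
    """
    rng = child_rng(config.seed, "peaks")
    per_rep: dict[tuple[str, str, str], PeakSet] = {}
    multimap: dict[str, tuple[PeakSet, PeakSet]] = {}
    repeat_site: dict[str, list[GenomicInterval]] = {sp: [] for sp in config.species}
    for sp in config.species:
        for iv in genomes.repeat_tracks.get(sp, []):
            repeat_site[sp].append(iv)

    repeat_species_of = {}
    for sp in config.species:
        for iv in genomes.repeat_tracks.get(sp, []):
            rid = iv.id.split(":")[0]
            repeat_species_of[rid] = sp

    for sp in config.species:
        unique_pool: list[GenomicInterval] = []
        for tissue in config.tissues:
            for r in range(1, config.replicates_per_group + 1):
                rep = f"r{r}"
                ivs = []
                for rid, base in genomes.region_coords[sp].items():
                    if repeat_species_of.get(rid) == sp:
                        continue  # no unique-mapping enrichment at repeats
                    if rng.random() < 0.03:
                        continue  # replicate dropout
                    if rng.random() < 0.10:
                        # narrow summit call, to be rescued by min-width extension
                        center = (base.start + base.end) // 2
                        half = int(rng.integers(100, 301))
                        s, e = center - half, center + half
                    else:
                        s = base.start + int(rng.integers(-100, 101))
                        e = base.end + int(rng.integers(-100, 101))
                    if e - s < 200:
                        e = s + 200
                    ivs.append(
                        GenomicInterval(sp, base.chrom, max(0, s), e, id=f"{rid}:{tissue}:{rep}")
                    )
                per_rep[(sp, tissue, rep)] = PeakSet(sp, tissue, rep, ivs)
                unique_pool.extend(ivs)
        unique_merged = PeakSet(
            sp,
            "pooled",
            "unique",
            [
                replace(iv, id=f"u{k}")
                for k, (iv, _) in enumerate(
                    _merge_anonymous(unique_pool)
                )
            ],
        )
        mm_pool = list(unique_merged.intervals)
        for iv in repeat_site[sp]:
            mm_pool.append(replace(iv, id=None))
        multimap_merged = PeakSet(
            sp,
            "pooled",
            "multimap",
            [
                replace(iv, id=f"m{k}")
                for k, (iv, _) in enumerate(_merge_anonymous(mm_pool))
            ],
        )
        multimap[sp] = (unique_merged, multimap_merged)
    return per_rep, multimap


def _merge_anonymous(ivs):
    from cregatlas.intervals import merge_stitch

    if not ivs:
        return []
    return merge_stitch([replace(iv, id=None) for iv in ivs], min_overlap=1)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def make_design(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet: species x tissue x replicate, replicate = batch.

    Library sizes are drawn log-normal (sigma 0.2) around 30 M reads so
    normalization is exercised; replicates sit in separate batches,
    mirroring the replicate-batch design of the study the statistics
    assume.
    """
    rng = child_rng(config.seed, "design")
    rows = []
    for sp in config.species:
        for tissue in config.tissues:
            for r in range(1, config.replicates_per_group + 1):
                rows.append(
                    {
                        "sample_id": f"{sp}_{tissue}_r{r}",
                        "species": sp,
                        "tissue": tissue,
                        "replicate": f"r{r}",
                        "batch": f"b{r}",
                        "library_size": int(rng.lognormal(np.log(3e7), 0.2)),
                    }
                )
    return pd.DataFrame(rows)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB with variance mean + alpha mean^2 (Poisson in the alpha->0 limit)."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(
    truth: pd.DataFrame,
    design: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Raw NB counts over all candidate regions for every sample.

    Cell (i, j) ~ NB(mean = library-scaled planted mean of region i in
    sample j's species, dispersion = config.nb_dispersion).  Planted
    effects apply to both tissues identically.
    """
    _require_valid(config)
    unknown = set(design["species"]) - set(config.species)
    if unknown:
        raise ValueError(f"design names unknown species {sorted(unknown)}")
    rng = child_rng(config.seed, "counts")
    lib = design["library_size"].to_numpy(dtype=float)
    lib_factor = lib / lib.mean()
    cols = {}
    for j, row in enumerate(design.itertuples(index=False)):
        mu = truth[f"mean_{row.species}"].to_numpy() * lib_factor[j]
        cols[row.sample_id] = _nb_draw(rng, mu, config.nb_dispersion)
    return pd.DataFrame(cols, index=truth["region_id"].to_numpy())


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_alignments(
    truth: pd.DataFrame,
    config: SimulationConfig,
    invalid_rate: float = 0.0,
) -> dict[str, AlignmentColumns]:
    """Four-way alignment columns with planted hominin-branch changes.

    Substituted columns carry a shared human/chimp base differing from
    the (ancestral) base kept by both monkeys; the substitution rate is
    ``hominin_substitution_rate_gain`` for planted hominin gains and the
    background rate otherwise.  ``invalid_rate`` optionally masks a
    fraction of columns as unaligned.
    """
    rng = child_rng(config.seed, "alignments")
    hu, ch, rm, mm = config.species
    out: dict[str, AlignmentColumns] = {}
    for row in truth.itertuples(index=False):
        L = row.end - row.start
        ref = _BASES[rng.integers(0, 4, L)]
        rate = (
            config.hominin_substitution_rate_gain
            if row.true_class == "hominin_gain"
            else config.hominin_substitution_rate_background
        )
        sub = rng.random(L) < rate
        idx = np.searchsorted(_BASES, ref)  # ACGT alphabet index of each ref base
        derived = _BASES[(idx + rng.integers(1, 4, L)) % 4]
        hominin = ref.copy()
        hominin[sub] = derived[sub]
        valid = rng.random(L) >= invalid_rate if invalid_rate > 0 else None
        out[row.region_id] = AlignmentColumns(
            region_id=row.region_id,
            bases={
                hu: hominin.tobytes().decode("ascii"),
                ch: hominin.tobytes().decode("ascii"),
                rm: ref.tobytes().decode("ascii"),
                mm: ref.tobytes().decode("ascii"),
            },
            valid=valid,
        )
    return out


# ---------------------------------------------------------------------------
# annotation sets
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSets:
    celltype_sets: dict[str, list[GenomicInterval]]
    asd_down: list[GenomicInterval]
    ad_down: list[GenomicInterval]
    tss: pd.DataFrame
    loops: pd.DataFrame
    conservation: pd.DataFrame
    open_chromatin_mask: list[GenomicInterval]


def simulate_annotation_sets(
    truth: pd.DataFrame, config: SimulationConfig
) -> AnnotationSets:
    """Cell-type/disease region sets, TSS, loops, conservation and mask.

    Cell-type and ASD membership follow the truth table exactly (the
    planted fractions live in :func:`make_truth`); conservation is
    planted lower at hominin gains than at stable regions, mirroring the
    reduced-constraint signature the scores should recover.
    """
    rng = child_rng(config.seed, "annotation")
    ref = config.reference
    celltype_sets: dict[str, list[GenomicInterval]] = {ct: [] for ct in CELL_TYPES}
    asd_down: list[GenomicInterval] = []
    ad_down: list[GenomicInterval] = []
    cons_rows = []
    mask: list[GenomicInterval] = []
    tss_rows = []
    loop_rows = []
    gene_k = 0
    for k, row in enumerate(truth.itertuples(index=False)):
        center = (row.start + row.end) // 2
        if row.true_cell_type:
            celltype_sets[row.true_cell_type].append(
                GenomicInterval(ref, row.chrom, center - 250, center + 250, id=f"{row.region_id}:ct")
            )
        if row.true_asd_down:
            asd_down.append(
                GenomicInterval(ref, row.chrom, center - 300, center + 300, id=f"{row.region_id}:asd")
            )
        if rng.random() < 0.05:
            ad_down.append(
                GenomicInterval(ref, row.chrom, center - 300, center + 300, id=f"{row.region_id}:ad")
            )
        base_score = 0.45 if row.true_class == "hominin_gain" else 0.6
        for s in range(row.start, row.end, 200):
            e = min(s + 200, row.end)
            val = float(np.clip(base_score + rng.normal(0.0, 0.08), 0.0, 1.0))
            cons_rows.append((row.chrom, s, e, val))
        q = (row.end - row.start) // 4
        mask.append(GenomicInterval(ref, row.chrom, row.start + q, row.end - q))
        if k % 3 == 0:
            # promoter-side TSS within the 1 kb window
            pos = row.start - int(rng.integers(0, 800))
            strand = "+" if rng.random() < 0.5 else "-"
            tss_rows.append((row.chrom, max(0, pos), max(1, pos + 1), f"gene{gene_k}",
                             float(rng.uniform(1, 10)), strand))
            gene_k += 1
        elif k % 3 == 1:
            # distal TSS; some regions additionally get a loop to it
            pos = row.end + int(rng.integers(5_000, 50_000))
            score = float(rng.uniform(1, 10)) if rng.random() < 0.8 else 0.0
            strand = "+" if rng.random() < 0.5 else "-"
            tss_rows.append((row.chrom, pos, pos + 1, f"gene{gene_k}", score, strand))
            if rng.random() < 0.3:
                loop_rows.append(
                    (row.chrom, row.start, row.end, row.chrom, pos - 500, pos + 500,
                     f"loop_{row.region_id}")
                )
            gene_k += 1
    tss = pd.DataFrame(
        tss_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    loops = pd.DataFrame(
        loop_rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name"],
    )
    conservation = pd.DataFrame(cons_rows, columns=["chrom", "start", "end", "value"])
    return AnnotationSets(
        celltype_sets=celltype_sets,
        asd_down=asd_down,
        ad_down=ad_down,
        tss=tss,
        loops=loops,
        conservation=conservation,
        open_chromatin_mask=mask,
    )


# ---------------------------------------------------------------------------
# 4C
# ---------------------------------------------------------------------------


def simulate_fourc(
    config: SimulationConfig,
    n_fragments: int | None = None,
    flat: bool = False,
    noise: bool = True,
) -> FragmentProfile:
    """A fragment-end contact profile decaying away from the viewpoint."""
    rng = child_rng(config.seed, "fourc")
    n = n_fragments if n_fragments is not None else config.fourc_n_fragments
    if n < 2:
        raise ValueError("need at least 2 fragment ends")
    gaps = rng.integers(500, 4001, n)
    positions = 1_000_000 + np.cumsum(gaps)
    viewpoint = int(positions[n // 2])
    if flat:
        mean = np.full(n, config.fourc_peak_mean)
    else:
        dist = np.abs(positions - viewpoint)
        mean = config.fourc_peak_mean * np.exp(-dist / config.fourc_decay_bp) + 1.0
    counts = _nb_draw(rng, mean, config.nb_dispersion) if noise else mean
    return FragmentProfile(
        chrom="chr1", viewpoint=viewpoint, positions=positions, counts=np.asarray(counts, dtype=float)
    )


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    truth: pd.DataFrame
    genomes: GenomeBundle
    peaks: dict[tuple[str, str, str], PeakSet]
    multimap_peaks: dict[str, tuple[PeakSet, PeakSet]]
    design: pd.DataFrame
    counts: pd.DataFrame
    alignments: dict[str, AlignmentColumns]
    annotations: AnnotationSets
    fourc: FragmentProfile


def simulate_bundle(config: SimulationConfig) -> SimulatedBundle:
    """Generate every pipeline input from one config/seed."""
    truth = make_truth(config)
    genomes = simulate_genomes(config, truth)
    peaks, multimap = simulate_peaks(config, truth, genomes)
    design = make_design(config)
    counts = simulate_counts(truth, design, config)
    alignments = simulate_alignments(truth, config)
    annotations = simulate_annotation_sets(truth, config)
    fourc = simulate_fourc(config)
    return SimulatedBundle(
        config=config,
        truth=truth,
        genomes=genomes,
        peaks=peaks,
        multimap_peaks=multimap,
        design=design,
        counts=counts,
        alignments=alignments,
        annotations=annotations,
        fourc=fourc,
    )
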