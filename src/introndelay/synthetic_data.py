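"""Generators for synthetic embryo transcriptomes with known ground truth.

The central piece is a mechanistic simulator of abortive transcription during
the rapid syncytial cell cycles of the early *Drosophila* embryo: RNA
polymerases initiate on zygotic genes during interphase, elongate at a fixed
rate, and nascent transcripts still attached at the next mitosis are released
from the condensing chromosomes and degraded. A transcript can therefore be
completed only if its primary length fits within elongation_rate x interphase
duration — the "intron delay" constraint on long genes. Maternal transcripts
are deposited as mature mRNA at t=0 and only decay.

Also provided: a genome/annotation generator, a strand-aware read sampler for
poly-A and total-RNA libraries, a multi-species orthologous-intron evolver,
and a planted-effect expression matrix for threshold-selection experiments.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .models import (
    MIN_INTRON,
    CellCycleSchedule,
    ConfigurationError,
    GeneModel,
    InputError,
    PhylogenyConfig,
    SimulationConfig,
    TranscriptPool,
)

_MIN_EXON = 50

DEFAULT_LENGTH_SPEC = {
    "median": 2500.0,  # bp; log-normal median of primary transcript length
    "sigma": 1.0,  # SD of log length; puts ~24% of genes at >= 5 kb
    "min_length": 300,
    "max_length": 150_000,
}


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _gene_structure(rng: np.random.Generator, length: int) -> Tuple[Tuple[int, int], ...]:
    """Partition a primary transcript of ``length`` bp into exons and introns
    (relative coordinates). Intron count scales with gene length, so short
    genes are frequently intronless, as in real fly annotations."""
    max_k = max(0, (length - _MIN_EXON) // (_MIN_EXON + MIN_INTRON))
    # ~20% of fly genes are intronless; intron count grows with gene length
    k = int(min(rng.poisson(0.5 + length / 2500.0), max_k))
    while k > 0 and _MIN_EXON * (k + 1) + MIN_INTRON * k > length:
        k -= 1
    if k == 0:
        return ((0, length),)
    budget = length - _MIN_EXON * (k + 1) - MIN_INTRON * k
    # intron expansions: heavy-tailed, like fly intron length distributions
    extra_i = np.floor(rng.lognormal(np.log(30.0), 1.2, size=k)).astype(int)
    if extra_i.sum() > budget:
        scale = budget / max(extra_i.sum(), 1)
        extra_i = np.floor(extra_i * scale).astype(int)
    introns = MIN_INTRON + extra_i
    exon_budget = length - introns.sum() - _MIN_EXON * (k + 1)
    parts = rng.dirichlet(np.ones(k + 1))
    exons = _MIN_EXON + rng.multinomial(exon_budget, parts)
    rel = []
    pos = 0
    for j in range(k + 1):
        rel.append((pos, pos + int(exons[j])))
        pos += int(exons[j])
        if j < k:
            pos += int(introns[j])
    # rounding in the intron scaling can leave a shortfall; absorb in last exon
    last_s, last_e = rel[-1]
    rel[-1] = (last_s, last_e + (length - pos))
    return tuple(rel)


def make_genome(
    n_genes: int,
    length_spec: Optional[dict] = None,
    origin_fractions: Tuple[float, float] = (0.6, 0.4),
    seed: int = 0,
    chrom: str = "chr2L",
) -> Tuple[List[GeneModel], pd.DataFrame]:
    """Generate ``n_genes`` non-overlapping gene models plus a maternal/zygotic
    classification table.

    ``length_spec`` keys: median, sigma (log-normal primary length), min_length,
    max_length, and optionally ``maternal_median``/``zygotic_median`` to give
    the two origin classes different length distributions, or ``lengths`` to
    supply explicit primary lengths. ``origin_fractions`` is
    (maternal, zygotic) and must sum to 1.
    """
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    if abs(sum(origin_fractions) - 1.0) > 1e-9 or min(origin_fractions) < 0:
        raise ConfigurationError("origin_fractions must be non-negative and sum to 1")
    spec = dict(DEFAULT_LENGTH_SPEC)
    spec.update(length_spec or {})
    if spec.get("lengths") is None and (spec["sigma"] <= 0 or spec["median"] <= 0):
        raise ConfigurationError("length_spec median and sigma must be > 0")
    if spec["min_length"] < _MIN_EXON:
        raise ConfigurationError(f"min_length must be >= {_MIN_EXON}")

    rng = np.random.default_rng(seed)
    n_mat = int(round(origin_fractions[0] * n_genes))
    origins = np.array(["maternal"] * n_mat + ["zygotic"] * (n_genes - n_mat))
    rng.shuffle(origins)

    if spec.get("lengths") is not None:
        lengths = np.asarray(spec["lengths"], dtype=int)
        if lengths.size != n_genes:
            raise ConfigurationError("explicit lengths must match n_genes")
    else:
        med = {
            "maternal": spec.get("maternal_median", spec["median"]),
            "zygotic": spec.get("zygotic_median", spec["median"]),
        }
        mu = np.log([med[o] for o in origins])
        lengths = np.exp(rng.normal(mu, spec["sigma"]))
        lengths = np.clip(lengths, spec["min_length"], spec["max_length"]).astype(int)

    genes: List[GeneModel] = []
    cursor = 1000
    width = len(str(n_genes))
    for i in range(n_genes):
        rel = _gene_structure(rng, int(lengths[i]))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = tuple((cursor + s, cursor + e) for s, e in rel)
        genes.append(
            GeneModel(
                gene_id=f"g{i:0{width}d}",
                chrom=chrom,
                strand=strand,
                exons=exons,
                origin=str(origins[i]),
            )
        )
        cursor += int(lengths[i]) + int(rng.integers(200, 2000))
    classes = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "origin": [g.origin for g in genes]}
    )
    return genes, classes


# ---------------------------------------------------------------------------
# abortive-transcription timecourse simulator
# ---------------------------------------------------------------------------

def _split_segments(schedule: CellCycleSchedule, sample_times: Sequence[float]):
    """Chronological sub-segments, split at sample times. Yields tuples
    (phase, t0, t1, cycle, phase_start, samples_at_t1)."""
    eps = 1e-9
    samples = sorted(set(float(t) for t in sample_times))
    out = []
    for cycle, phase, t0, t1 in schedule.segments():
        cuts = [t for t in samples if t0 + eps < t < t1 - eps]
        edges = [t0] + cuts + [t1]
        for j in range(len(edges) - 1):
            a, b = edges[j], edges[j + 1]
            at_sample = any(abs(t - b) <= eps for t in samples)
            out.append((phase, a, b, cycle, j == 0, at_sample))
    return out


def simulate_timecourse(
    genes: Sequence[GeneModel],
    schedule: CellCycleSchedule,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> Dict[float, TranscriptPool]:
    """Simulate transcript populations over the cell-cycle schedule and return
    a :class:`TranscriptPool` snapshot at each requested sample time.

    Mechanism per interphase: eligible genes initiate as a Poisson process,
    polymerases advance at ``elongation_rate`` bp/min, and transcripts whose
    polymerase reaches the end of the primary transcript convert to mature
    mRNA (splicing is instantaneous). At each mitosis entry every nascent
    transcript is destroyed with probability ``abort_prob_at_mitosis``.
    Mature mRNAs decay exponentially at the origin-appropriate rate. Zygotic
    initiation starts at ``schedule.zga_cycle``; maternal genes are deposited
    as mature mRNA at t=0 and re-initiate only if
    ``config.maternal_zygotic_onset`` is set.

    With ``config.independent_timepoints`` (the default) each sample time is
    taken from its own independently simulated embryo pool, matching
    timecourse designs where every collection window uses different embryos.
    """
    if not genes:
        raise ConfigurationError("no genes to simulate")
    total = schedule.total_duration
    for t in config.sample_times:
        if not 0.0 <= t <= total:
            raise InputError(f"sample time {t} outside schedule span [0, {total}]")
    base_seed = config.seed if seed is None else seed
    if config.independent_timepoints and len(config.sample_times) > 1:
        streams = np.random.SeedSequence(base_seed).spawn(len(config.sample_times))
        out: Dict[float, TranscriptPool] = {}
        for t, ss in zip(sorted(set(float(x) for x in config.sample_times)), streams):
            out[t] = _run_embryo(genes, schedule, config, (t,), np.random.default_rng(ss))[t]
        return out
    return _run_embryo(
        genes, schedule, config, config.sample_times, np.random.default_rng(base_seed)
    )


def _run_embryo(
    genes: Sequence[GeneModel],
    schedule: CellCycleSchedule,
    config: SimulationConfig,
    sample_times: Sequence[float],
    rng: np.random.Generator,
) -> Dict[float, TranscriptPool]:
    """Simulate one stochastic embryo and snapshot it at ``sample_times``."""

    n = len(genes)
    gene_ids = tuple(g.gene_id for g in genes)
    L = np.array([g.primary_length for g in genes], dtype=float)
    is_zyg = np.array([g.origin == "zygotic" for g in genes])
    decay = np.where(is_zyg, config.zygotic_decay_rate, config.maternal_decay_rate)

    complete = np.zeros(n, dtype=np.int64)
    n_mat = int((~is_zyg).sum())
    if n_mat:
        complete[~is_zyg] = rng.poisson(config.maternal_abundance, size=n_mat)
    initiated = complete.copy()  # deposits count as initiated-and-completed at t=0
    completed = complete.copy()
    aborted = np.zeros(n, dtype=np.int64)
    nas_g = np.empty(0, dtype=np.int64)
    nas_p = np.empty(0, dtype=float)

    v = config.elongation_rate
    r = config.initiation_rate
    snapshots: Dict[float, TranscriptPool] = {}

    def snapshot(t: float):
        snapshots[t] = TranscriptPool(
            time=t,
            gene_ids=gene_ids,
            complete=complete.copy(),
            nascent_gene_index=nas_g.copy(),
            nascent_positions=nas_p.copy(),
            initiated=initiated.copy(),
            completed=completed.copy(),
            aborted=aborted.copy(),
        )

    last_sample = max(float(t) for t in sample_times)
    if 0.0 in set(float(t) for t in sample_times):
        snapshot(0.0)

    for phase, t0, t1, cycle, phase_start, is_sample in _split_segments(
        schedule, sample_times
    ):
        if t0 >= last_sample:
            break
        dt = t1 - t0
        if phase == "mitosis":
            if phase_start and len(nas_p) and config.abort_prob_at_mitosis > 0:
                kill = rng.random(len(nas_p)) < config.abort_prob_at_mitosis
                np.add.at(aborted, nas_g[kill], 1)
                nas_g, nas_p = nas_g[~kill], nas_p[~kill]
            complete = rng.binomial(complete, np.exp(-decay * dt))
        else:
            # decay of mRNAs present at t0
            complete = rng.binomial(complete, np.exp(-decay * dt))
            # elongation of pre-existing polymerases
            if len(nas_p):
                t_c = t0 + (L[nas_g] - nas_p) / v if v > 0 else np.full(len(nas_p), np.inf)
                nas_p = nas_p + v * dt
                done = nas_p >= L[nas_g]
                if done.any():
                    g_done = nas_g[done]
                    np.add.at(completed, g_done, 1)
                    surv = rng.random(g_done.size) < np.exp(
                        -decay[g_done] * (t1 - t_c[done])
                    )
                    np.add.at(complete, g_done[surv], 1)
                    nas_g, nas_p = nas_g[~done], nas_p[~done]
            # new initiations on eligible genes
            elig = is_zyg & (cycle >= schedule.zga_cycle)
            if config.maternal_zygotic_onset is not None:
                elig = elig | (~is_zyg & (t1 > config.maternal_zygotic_onset))
            elig_idx = np.flatnonzero(elig)
            if r > 0 and elig_idx.size and v >= 0:
                k = rng.poisson(r * dt, size=elig_idx.size)
                if k.sum():
                    g_new = np.repeat(elig_idx, k)
                    np.add.at(initiated, g_new, 1)
                    u = rng.uniform(t0, t1, size=g_new.size)
                    pos = v * (t1 - u)
                    done = pos >= L[g_new]
                    if done.any():
                        g_done = g_new[done]
                        np.add.at(completed, g_done, 1)
                        t_c = u[done] + L[g_done] / v
                        surv = rng.random(g_done.size) < np.exp(
                            -decay[g_done] * (t1 - t_c)
                        )
                        np.add.at(complete, g_done[surv], 1)
                    nas_g = np.concatenate([nas_g, g_new[~done]])
                    nas_p = np.concatenate([nas_p, pos[~done]])
        if is_sample:
            snapshot(t1)

    return snapshots


def pools_to_expression(pools: Dict[float, TranscriptPool]) -> pd.DataFrame:
    """Mature-mRNA counts as a genes x sample-times matrix."""
    times = sorted(pools)
    first = pools[times[0]]
    data = {f"t{i}": pools[t].complete for i, t in enumerate(times)}
    df = pd.DataFrame(data, index=list(first.gene_ids))
    df.index.name = "gene_id"
    return df


def truth_table(pools: Dict[float, TranscriptPool]) -> pd.DataFrame:
    """Long-format per-gene, per-time truth: complete/nascent/counter columns."""
    rows = []
    for t in sorted(pools):
        p = pools[t]
        nascent_counts = np.bincount(p.nascent_gene_index, minlength=len(p.gene_ids))
        for i, gid in enumerate(p.gene_ids):
            rows.append(
                {
                    "time": t,
                    "gene_id": gid,
                    "complete": int(p.complete[i]),
                    "nascent": int(nascent_counts[i]),
                    "initiated": int(p.initiated[i]),
                    "completed": int(p.completed[i]),
                    "aborted": int(p.aborted[i]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------

def _valid_starts(segs: np.ndarray, clip: float, rl: int) -> np.ndarray:
    """Per-segment counts of read start positions fully inside exonic sequence
    of the transcript prefix [0, clip)."""
    lo = segs[:, 0]
    hi = np.minimum(segs[:, 1], clip)
    return np.maximum((hi - lo).astype(int) - rl + 1, 0)


def sample_reads(
    pool: TranscriptPool,
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    seed: Optional[int] = None,
    with_truth: bool = False,
) -> pd.DataFrame:
    """Draw single-end reads from a transcript pool as a 6-column BED table.

    In ``polyA`` mode, read starts are sampled uniformly over the exonic
    (mature) sequence of complete transcripts only. In ``total`` mode, each
    nascent transcript additionally contributes the exonic part of its
    transcribed prefix. Reads are allocated across transcripts by a
    multinomial on available sequence mass and never span exon junctions
    (junction reads are a negligible fraction at 50 bp and are omitted).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rl = config.read_length
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    if with_truth:
        cols = cols + ["source_gene"]
    gene_ids = list(pool.gene_ids)
    if len(genes) != len(gene_ids) or any(
        g.gene_id != gid for g, gid in zip(genes, gene_ids)
    ):
        gmap = {g.gene_id: g for g in genes}
        try:
            genes = [gmap[gid] for gid in gene_ids]
        except KeyError as e:
            raise InputError(f"pool gene {e} missing from annotation") from None

    segs = [np.array(g.exon_segments_transcript(), dtype=float) for g in genes]
    mature_vs = np.array(
        [int(_valid_starts(s, np.inf, rl).sum()) for s in segs], dtype=float
    )
    active = pool.complete > 0
    if np.any(active & (mature_vs == 0)):
        bad = [gene_ids[i] for i in np.flatnonzero(active & (mature_vs == 0))]
        raise InputError(
            f"read_length {rl} exceeds every exon of expressed gene(s) {bad[:3]}"
        )

    w_complete = pool.complete * mature_vs
    # per-gene nascent mass (total mode only)
    w_nascent = np.zeros(len(genes))
    nascent_by_gene: Dict[int, np.ndarray] = {}
    if config.library_mode == "total" and len(pool.nascent_positions):
        order = np.argsort(pool.nascent_gene_index, kind="stable")
        gidx = pool.nascent_gene_index[order]
        posn = pool.nascent_positions[order]
        for i in np.unique(gidx):
            p_i = posn[gidx == i]
            nascent_by_gene[int(i)] = p_i
            w_nascent[i] = sum(
                _valid_starts(segs[i], p, rl).sum() for p in p_i
            )

    weights = w_complete + w_nascent
    total_w = weights.sum()
    if total_w <= 0 or config.reads_per_timepoint == 0:
        return pd.DataFrame(columns=cols)

    per_gene = rng.multinomial(config.reads_per_timepoint, weights / total_w)
    chroms, starts, ends, strands, sources = [], [], [], [], []

    def draw(g: GeneModel, seg: np.ndarray, clips: np.ndarray, clip_w: np.ndarray, k: int):
        """Sample k read start positions from prefixes of gene g; ``clips`` are
        prefix lengths with multinomial weights clip_w (valid-start counts)."""
        by_clip = rng.multinomial(k, clip_w / clip_w.sum())
        for clip, kk in zip(clips, by_clip):
            if kk == 0:
                continue
            vs = _valid_starts(seg, clip, rl)
            tot = vs.sum()
            if tot == 0:
                continue
            by_seg = rng.multinomial(kk, vs / tot)
            for (ts, te), v_j, k_j in zip(seg, vs, by_seg):
                if k_j == 0:
                    continue
                off = rng.integers(0, v_j, size=k_j)
                for o in off:
                    a, b = g.transcript_to_genomic(int(ts) + int(o), int(ts) + int(o) + rl)
                    chroms.append(g.chrom)
                    starts.append(a)
                    ends.append(b)
                    strands.append(g.strand)
                    if with_truth:
                        sources.append(g.gene_id)

    for i, k in enumerate(per_gene):
        if k == 0:
            continue
        g = genes[i]
        clips = [float(L) for L in ([g.primary_length] if w_complete[i] > 0 else [])]
        clip_w = [w_complete[i]] if w_complete[i] > 0 else []
        for p in nascent_by_gene.get(i, ()):
            vsum = _valid_starts(segs[i], p, rl).sum()
            if vsum > 0:
                clips.append(float(p))
                clip_w.append(float(vsum))
        if not clips:
            continue
        draw(g, segs[i], np.array(clips), np.array(clip_w, dtype=float), int(k))

    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.array(starts, dtype=int),
            "end": np.array(ends, dtype=int),
            "name": [f"read{j}" for j in range(len(starts))],
            "score": 0,
            "strand": strands,
        }
    )
    if with_truth:
        df["source_gene"] = sources
    return df


# ---------------------------------------------------------------------------
# orthologous intron evolution
# ---------------------------------------------------------------------------

def evolve_orthologous_introns(
    genes: Sequence[GeneModel],
    phylo: PhylogenyConfig,
    constrained_ids: Optional[Set[str]] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Evolve each intron's log-length by independent Gaussian steps down a
    star phylogeny and return total orthologous intron length per gene and
    species. Genes in ``constrained_ids`` use ``sigma_constrained`` (purifying
    selection on intron length); all others use ``sigma_neutral``. Lengths are
    floored at ``phylo.min_intron``. Single-exon genes get all-zero rows."""
    constrained_ids = set(constrained_ids or ())
    known = {g.gene_id for g in genes}
    unknown = constrained_ids - known
    if unknown:
        raise InputError(f"constrained_ids not in annotation: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(phylo.seed if seed is None else seed)
    out = np.zeros((len(genes), len(phylo.species)))
    for gi, g in enumerate(genes):
        introns = np.array(g.intron_lengths, dtype=float)
        if introns.size == 0:
            continue
        sigma = (
            phylo.sigma_constrained if g.gene_id in constrained_ids else phylo.sigma_neutral
        )
        logl = np.log(introns)
        for si, b in enumerate(phylo.branch_lengths):
            if b == 0 or sigma == 0:
                evolved = introns
            else:
                steps = rng.normal(0.0, sigma * b, size=introns.size)
                evolved = np.maximum(np.round(np.exp(logl + steps)), phylo.min_intron)
            out[gi, si] = evolved.sum()
    df = pd.DataFrame(out, index=[g.gene_id for g in genes], columns=list(phylo.species))
    df.index.name = "gene_id"
    return df


# ---------------------------------------------------------------------------
# planted-effect expression matrix
# ---------------------------------------------------------------------------

def make_planted_delay_matrix(
    n_genes: int = 800,
    n_timepoints: int = 6,
    threshold: int = 5000,
    effect: float = 3.0,
    noise_sd: float = 0.7,
    seed: int = 0,
    length_spec: Optional[dict] = None,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Expression matrix (log2-like units) where genes with primary length
    >= ``threshold`` carry an early-expression deficit of ``effect`` units
    that relaxes linearly to zero by the last timepoint — a statistically
    planted analogue of intron delay with exactly known truth. Returns
    (matrix, lengths)."""
    if n_genes < 2 or n_timepoints < 2:
        raise ConfigurationError("need at least 2 genes and 2 timepoints")
    spec = dict(DEFAULT_LENGTH_SPEC)
    spec.update(length_spec or {})
    rng = np.random.default_rng(seed)
    lengths = np.exp(rng.normal(np.log(spec["median"]), spec["sigma"], size=n_genes))
    lengths = np.clip(lengths, spec["min_length"], spec["max_length"]).astype(int)
    base = rng.normal(6.0, 1.0, size=n_genes)
    delayed = (lengths >= threshold).astype(float)
    t_frac = np.arange(n_timepoints) / (n_timepoints - 1)
    mat = (
        base[:, None]
        - effect * delayed[:, None] * (1.0 - t_frac[None, :])
        + rng.normal(0.0, noise_sd, size=(n_genes, n_timepoints))
    )
    ids = [f"g{i:04d}" for i in range(n_genes)]
    df = pd.DataFrame(mat, index=ids, columns=[f"t{i}" for i in range(n_timepoints)])
    df.index.name = "gene_id"
    return df, pd.Series(lengths, index=ids, name="primary_length")
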