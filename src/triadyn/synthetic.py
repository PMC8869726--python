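"""Synthetic wheat-grain time-course data with planted ground truth.

The generator emulates the study design the pipeline targets: a
6-time-point (0-10 days after pollination, step 2) grain-development
course with 3 biological replicates, expression organised in subgenome
triads.  For each triad it plants a bias category (Balance, one-homoeolog
dominant / suppressed per subgenome, or Low), draws relative homoeolog
contributions from a Dirichlet around the category centroid, modulates
the triad total FPKM by a temporal cluster template, plants step fold
changes between designated adjacent time points, and finally realises
sequencing counts with a negative binomial model via the inverse of the
FPKM definition.  Annotation maps (TF families, pathway terms) are
planted with enriched term/set pairs.  Everything needed to score
recovery is returned as a :class:`SyntheticTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .triad_bias import CATEGORIES, CENTROIDS, LOW, EXPRESSED_THRESHOLD

#: Dirichlet parameters must be strictly positive; zero centroid
#: components are clamped to this before scaling by the concentration.
CENTROID_EPS = 1e-3

# planted totals are kept out of this band around the expressed-triad
# threshold so that the planted Low / expressed state is unambiguous
# under count noise
_GUARD_LOW = 0.5
_GUARD_HIGH = 2.0


def _default_category_mix() -> dict:
    # mirrors the observed composition of a deep grain time course:
    # ~79.8% of triads expressed, of which 72.13% balanced, 20.97%
    # single-homoeolog suppressed and 6.90% single-homoeolog dominant
    e = 11398 / 14284
    mix = {"Balance": 0.7213 * e}
    for s in "ABD":
        mix[f"{s} suppressed"] = 0.2097 * e / 3
    for s in "ABD":
        mix[f"{s} dominant"] = 0.0690 * e / 3
    mix[LOW] = 1.0 - e
    return mix


@dataclass
class SimulationConfig:
    """Parameters of the synthetic data generator.

    Attributes
    ----------
    n_triads : number of A/B/D triads (3x genes).
    n_timepoints : time points, labelled 0, 2, 4, ... DAP.
    n_replicates : biological replicates per time point.
    category_mix : proportions over the seven bias categories plus Low;
        must sum to 1.
    bias_concentration : Dirichlet concentration (kappa) around the
        category centroid; may be ``inf`` for noise-free fractions.
    nb_dispersion : negative binomial dispersion alpha
        (variance = mu + alpha mu^2); 0 gives Poisson counts.
    base_expression_log_mean, base_expression_log_sd : natural-log
        parameters of the log-normal triad-total FPKM baseline.
    library_size_range : per-sample mapped-fragment totals, drawn
        log-uniformly.
    gene_length_range : transcript lengths in bp, drawn uniformly.
    n_clusters_planted : temporal template count (1 = flat profiles).
    de_fraction : fraction of expressed triads given a planted step
        fold change per adjacent contrast.
    de_log2fc : magnitude of the planted log2 fold change.
    switch_fraction : fraction of expressed triads whose bias category
        switches at one adjacent time-point boundary.
    n_terms, enrichment_fold, annotation_base_rate : annotation-map
        planting controls.
    seed : master seed; all randomness derives from it.
    """

    n_triads: int = 2000
    n_timepoints: int = 6
    n_replicates: int = 3
    category_mix: dict = field(default_factory=_default_category_mix)
    bias_concentration: float = 200.0
    nb_dispersion: float = 0.1
    base_expression_log_mean: float = 2.5
    base_expression_log_sd: float = 1.0
    library_size_range: tuple = (20_000_000, 40_000_000)
    gene_length_range: tuple = (500, 5000)
    n_clusters_planted: int = 4
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    switch_fraction: float = 0.1
    n_terms: int = 20
    enrichment_fold: float = 4.0
    annotation_base_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_triads < 0:
            raise ValueError("n_triads must be non-negative")
        for name in ("n_timepoints", "n_replicates", "n_clusters_planted", "n_terms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        unknown = set(self.category_mix) - set(CATEGORIES) - {LOW}
        if unknown:
            raise ValueError(f"unknown categories in category_mix: {sorted(unknown)}")
        vals = np.array(list(self.category_mix.values()), dtype=float)
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("category_mix entries must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("category_mix must sum to 1 within 1e-9")
        for name in ("bias_concentration", "nb_dispersion", "base_expression_log_sd",
                     "de_log2fc", "enrichment_fold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.de_fraction < 1):
            raise ValueError("de_fraction must lie in [0, 1)")
        if not (0 <= self.switch_fraction <= 1):
            raise ValueError("switch_fraction must lie in [0, 1]")
        for name in ("library_size_range", "gene_length_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must satisfy 0 < low <= high")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["library_size_range"] = list(d["library_size_range"])
        d["gene_length_range"] = list(d["gene_length_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("library_size_range", "gene_length_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted ground truth of one simulated dataset.

    category : long frame (triad_id, timepoint, category) — the planted
        bias state of every triad at every time point, Low wherever the
        planted total FPKM is at or below the expressed-triad threshold.
    cluster : per-gene planted temporal cluster label.
    de : long frame (gene_id, contrast, sign) of planted fold changes;
        genes/contrasts absent from the frame are planted null.
    enriched_terms : frame (set_label, term_id) of planted enrichments.
    planted_fpkm : genes x time points noise-free FPKM.
    """

    category: pd.DataFrame
    cluster: pd.Series
    de: pd.DataFrame
    enriched_terms: pd.DataFrame
    planted_fpkm: pd.DataFrame


@dataclass
class SyntheticDataset:
    counts: ExpressionMatrix
    lengths: pd.Series
    triads: pd.DataFrame
    tf_families: pd.DataFrame
    pathways: pd.DataFrame
    truth: SyntheticTruth
    config: SimulationConfig


def simulate_category_fractions(category: str, kappa: float, rng: np.random.Generator,
                                size: int | None = None) -> np.ndarray:
    """Draw (fA, fB, fD) from a Dirichlet centred on a category centroid.

    Zero centroid components are clamped to a small epsilon (Dirichlet
    parameters must be strictly positive), so the mean is the
    epsilon-adjusted centroid.  ``kappa=inf`` returns that mean exactly.
    """
    if category not in CENTROIDS:
        raise ValueError(f"unknown bias category {category!r}")
    if not kappa > 0:
        raise ValueError("kappa must be positive")
    centroid = np.maximum(CENTROIDS[category], CENTROID_EPS)
    centroid = centroid / centroid.sum()
    if np.isinf(kappa):
        out = np.tile(centroid, (size or 1, 1))
    else:
        out = rng.dirichlet(kappa * centroid, size=size or 1)
    return out[0] if size is None else out


def simulate_counts(mean_fpkm, length_bp, library_size, dispersion, rng: np.random.Generator):
    """Realise sequencing counts from planted FPKM.

    Inverts the FPKM definition to the expected fragment count
    mu = FPKM x length_bp x library_size / 1e9 and draws from a
    negative binomial with variance mu + dispersion * mu^2
    (gamma-Poisson mixture; Poisson when dispersion is 0).
    Broadcasts over array inputs.
    """
    fpkm = np.asarray(mean_fpkm, dtype=float)
    length = np.asarray(length_bp, dtype=float)
    lib = np.asarray(library_size, dtype=float)
    if (fpkm < 0).any() or (length <= 0).any() or (lib <= 0).any():
        raise ValueError("negative FPKM or non-positive length/library size")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    mu = fpkm * length * lib / 1e9
    if not np.all(np.isfinite(mu)) or np.any(mu > 1e12):
        raise ValueError("expected count overflow")
    if dispersion < 1e-12:
        return rng.poisson(mu)
    lam = np.where(mu > 0, rng.gamma(1.0 / dispersion, dispersion * np.maximum(mu, 1e-300)), 0.0)
    return rng.poisson(lam)


def temporal_templates(n_timepoints: int, n_clusters: int, amplitude: float = 1.5) -> np.ndarray:
    """Library of planted log2-scale temporal shapes, (n_clusters, T).

    Shapes mirror the qualitative cluster profiles of grain time
    courses: monotone rising / falling trends and uni-modal peaks or
    dips at early, mid or late development.  One cluster means flat
    profiles (no temporal structure).
    """
    if n_clusters == 1:
        return np.zeros((1, n_timepoints))
    u = np.linspace(0.0, 1.0, n_timepoints)

    def bump(center):
        b = np.exp(-((u - center) ** 2) / (2 * 0.18**2))
        return 2 * (b - b.mean())

    shapes = [
        2 * u - 1,           # rising
        1 - 2 * u,           # falling
        bump(0.5),           # mid peak
        -bump(0.5),          # mid dip
        bump(0.15),          # early peak
        bump(0.85),          # late peak
        -bump(0.15),         # early dip
        -bump(0.85),         # late dip
    ]
    if n_clusters > len(shapes):
        raise ValueError(f"at most {len(shapes)} planted templates are available")
    return amplitude * np.array(shapes[:n_clusters])


def _clear_guard_band(totals: np.ndarray) -> np.ndarray:
    """Rescale each triad's planted totals out of the threshold band.

    Planted per-time-point totals inside (_GUARD_LOW, _GUARD_HIGH) sit
    too close to the expressed-triad threshold for the planted state to
    survive count noise; each affected triad is scaled up until every
    total clears the band.
    """
    totals = totals.copy()
    for _ in range(totals.shape[1] + 1):
        in_band = (totals > _GUARD_LOW) & (totals < _GUARD_HIGH)
        rows = in_band.any(axis=1)
        if not rows.any():
            break
        mins = np.where(in_band, totals, np.inf).min(axis=1)
        scale = np.where(rows, _GUARD_HIGH * 1.0001 / np.where(rows, mins, 1.0), 1.0)
        totals *= scale[:, None]
    return totals


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset with planted truth.

    Deterministic given the config (including its seed): all randomness
    flows from per-purpose substreams spawned off one master seed, so
    identical configs yield byte-identical outputs.
    """
    n, T, R = config.n_triads, config.n_timepoints, config.n_replicates
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_struct = np.random.default_rng(streams[0])
    rng_frac = np.random.default_rng(streams[1])
    rng_de = np.random.default_rng(streams[2])
    rng_counts = np.random.default_rng(streams[3])
    rng_annot = np.random.default_rng(streams[4])

    timepoints = [str(2 * i) for i in range(T)]
    sample_ids = [f"DAP{tp}_R{r + 1}" for tp in timepoints for r in range(R)]
    samples = pd.DataFrame(
        {
            "timepoint": [tp for tp in timepoints for _ in range(R)],
            "replicate": [r + 1 for _ in timepoints for r in range(R)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    triad_ids = [f"TRI{i:05d}" for i in range(n)]
    triads = pd.DataFrame(
        {
            "gene_A": [f"{t}_A" for t in triad_ids],
            "gene_B": [f"{t}_B" for t in triad_ids],
            "gene_D": [f"{t}_D" for t in triad_ids],
        },
        index=pd.Index(triad_ids, name="triad_id"),
    )
    gene_ids = pd.Index(
        [g for t in triad_ids for g in (f"{t}_A", f"{t}_B", f"{t}_D")], name="gene_id"
    )

    lengths = pd.Series(
        rng_struct.integers(config.gene_length_range[0], config.gene_length_range[1] + 1,
                            size=len(gene_ids)),
        index=gene_ids,
        name="length_bp",
    )
    lo, hi = config.library_size_range
    lib_sizes = pd.Series(
        np.exp(rng_struct.uniform(np.log(lo), np.log(hi), size=len(sample_ids))).astype(int),
        index=samples.index,
        name="library_size",
    )

    mix_names = list(config.category_mix)
    mix_p = np.array([config.category_mix[c] for c in mix_names], dtype=float)
    mix_p = mix_p / mix_p.sum()
    base_cat = rng_struct.choice(mix_names, size=n, p=mix_p) if n else np.array([], dtype=object)

    # per-triad x time-point planted category, with switches at one
    # adjacent boundary for a fraction of expressed triads
    cat_grid = np.tile(base_cat[:, None], (1, T)).astype(object) if n else np.empty((0, T), object)
    expressed_mask = base_cat != LOW
    switch = expressed_mask & (rng_struct.random(n) < config.switch_fraction) if n else np.array([], bool)
    nonlow = [c for c in CATEGORIES]
    for i in np.flatnonzero(switch):
        boundary = rng_struct.integers(0, T - 1)  # switch between boundary and boundary+1
        choices = [c for c in nonlow if c != base_cat[i]]
        new_cat = choices[rng_struct.integers(0, len(choices))]
        cat_grid[i, boundary + 1:] = new_cat

    # triad-total planted FPKM: log-normal baseline x temporal template,
    # Low triads flat below the threshold
    baseline = np.where(
        expressed_mask,
        np.exp(rng_struct.normal(config.base_expression_log_mean,
                                 config.base_expression_log_sd, size=n)),
        rng_struct.uniform(0.05, _GUARD_LOW, size=n),
    ) if n else np.array([])
    cluster_idx = rng_struct.integers(0, config.n_clusters_planted, size=n) if n else np.array([], int)
    templates = temporal_templates(T, config.n_clusters_planted)
    totals = baseline[:, None] * 2.0 ** templates[cluster_idx] if n else np.empty((0, T))
    totals[~expressed_mask] = baseline[~expressed_mask, None]

    # planted step fold changes between adjacent time points
    de_records = []
    de_mult = np.ones((n, T))
    for j in range(T - 1):
        chosen = expressed_mask & (rng_de.random(n) < config.de_fraction)
        signs = np.where(rng_de.random(n) < 0.5, -1.0, 1.0)
        for i in np.flatnonzero(chosen):
            de_mult[i, j + 1:] *= 2.0 ** (signs[i] * config.de_log2fc)
            for sub in "ABD":
                de_records.append(
                    {"gene_id": f"{triad_ids[i]}_{sub}",
                     "contrast": f"{timepoints[j]}->{timepoints[j + 1]}",
                     "sign": int(signs[i])}
                )
    totals = totals * de_mult

    # homoeolog fractions per triad x time point
    fracs = np.full((n, T, 3), 1 / 3)
    for c in CATEGORIES:
        mask = cat_grid == c
        k = int(mask.sum())
        if k:
            fracs[mask] = simulate_category_fractions(c, config.bias_concentration,
                                                      rng_frac, size=k)

    # FPKM self-consistency: recomputed FPKM equals planted FPKM only
    # when sum(FPKM * length) over the transcriptome is ~1e9, so the
    # expressed triads are rescaled onto that realized scale (one
    # global factor, leaving fold changes and fractions untouched);
    # Low triads keep their planted sub-threshold totals, which carry
    # negligible library mass
    if n and expressed_mask.any():
        lens = lengths.to_numpy(float)
        s_t = np.zeros(T)
        for s in range(3):
            s_t += (totals * fracs[:, :, s] * lens[s::3, None]).sum(axis=0)
        totals[expressed_mask] *= 1e9 / s_t.mean()
    totals = _clear_guard_band(totals)

    # planted gene-level FPKM (genes x time points), A,B,D interleaved
    # per triad to match gene_ids ordering
    gene_fpkm = np.empty((3 * n, T))
    gene_fpkm[0::3] = totals * fracs[:, :, 0]
    gene_fpkm[1::3] = totals * fracs[:, :, 1]
    gene_fpkm[2::3] = totals * fracs[:, :, 2]
    planted_fpkm = pd.DataFrame(gene_fpkm, index=gene_ids, columns=timepoints)

    # realise counts
    counts = np.zeros((3 * n, len(sample_ids)), dtype=np.int64)
    for j, tp in enumerate(timepoints):
        for r in range(R):
            col = j * R + r
            counts[:, col] = simulate_counts(
                gene_fpkm[:, j], lengths.to_numpy(), lib_sizes.iloc[col],
                config.nb_dispersion, rng_counts,
            )
    counts_em = ExpressionMatrix(
        values=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        samples=samples,
        unit="counts",
    )

    # planted truth: Low wherever the planted total is at/below threshold
    truth_cat = cat_grid.copy()
    truth_cat[totals <= EXPRESSED_THRESHOLD] = LOW
    category_long = pd.DataFrame(
        {
            "triad_id": np.repeat(triad_ids, T),
            "timepoint": np.tile(timepoints, n),
            "category": truth_cat.reshape(-1),
        }
    )
    cluster = pd.Series(
        np.repeat([f"K{c + 1}" for c in cluster_idx], 3), index=gene_ids, name="cluster"
    )
    de = pd.DataFrame(de_records, columns=["gene_id", "contrast", "sign"])

    # annotation maps with planted enrichment
    tf_families, tf_truth = _plant_annotation(
        gene_ids, cluster, "TF", config, rng_annot
    )
    cat_sets = pd.Series(base_cat, index=pd.Index(triad_ids)).reindex(
        [g.rsplit("_", 1)[0] for g in gene_ids]
    )
    cat_sets.index = gene_ids
    pathways, pw_truth = _plant_annotation(
        gene_ids, cat_sets, "PW", config, rng_annot
    )
    enriched = pd.concat([tf_truth, pw_truth], ignore_index=True)

    truth = SyntheticTruth(
        category=category_long,
        cluster=cluster,
        de=de,
        enriched_terms=enriched,
        planted_fpkm=planted_fpkm,
    )
    return SyntheticDataset(
        counts=counts_em,
        lengths=lengths,
        triads=triads,
        tf_families=tf_families,
        pathways=pathways,
        truth=truth,
        config=config,
    )


def _plant_annotation(gene_ids, group_labels: pd.Series, prefix: str,
                      config: SimulationConfig, rng: np.random.Generator):
    """Assign annotation terms with half the terms planted enriched.

    Each planted term targets one gene group (cluster or bias
    category), where members carry the term at enrichment_fold times
    the background rate.
    """
    groups = [g for g in pd.unique(group_labels.dropna()) if g != LOW]
    records, truth_records = [], []
    n_enriched = config.n_terms // 2 if groups else 0
    base = config.annotation_base_rate
    for t in range(config.n_terms):
        term = f"{prefix}{t + 1:03d}"
        rate = np.full(len(gene_ids), base)
        if t < n_enriched:
            target = groups[t % len(groups)]
            rate = np.where(group_labels.to_numpy() == target,
                            min(1.0, config.enrichment_fold * base), base)
            truth_records.append({"set_label": str(target), "term_id": term})
        has = rng.random(len(gene_ids)) < rate
        for g in np.asarray(gene_ids)[has]:
            records.append({"gene_id": g, "term_id": term})
    ann = pd.DataFrame(records, columns=["gene_id", "term_id"])
    truth = pd.DataFrame(truth_records, columns=["set_label", "term_id"])
    return ann, truth


def simulate_cluster_profiles(n_genes: int, n_clusters: int, n_timepoints: int = 6,
                              noise_sd: float = 0.3, amplitude: float = 1.5,
                              rng: np.random.Generator | None = None):
    """Temporal FPKM profiles drawn from planted templates plus noise.

    Returns a (genes x time points) FPKM frame and the planted cluster
    labels; used for clustering-recovery validation independent of the
    full count simulation.
    """
    rng = rng or np.random.default_rng(0)
    templates = temporal_templates(n_timepoints, n_clusters, amplitude=amplitude)
    labels = rng.integers(0, n_clusters, size=n_genes)
    log2prof = templates[labels] + rng.normal(0.0, noise_sd, size=(n_genes, n_timepoints))
    base = np.exp(rng.normal(2.0, 0.8, size=n_genes))
    fpkm = base[:, None] * 2.0 ** log2prof
    idx = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene_id")
    profiles = pd.DataFrame(fpkm, index=idx, columns=[str(2 * i) for i in range(n_timepoints)])
    return profiles, pd.Series([f"K{c + 1}" for c in labels], index=idx, name="cluster")


def simulate_enrichment_data(n_background: int = 6000, set_size: int = 200,
                             n_terms: int = 20, fold: float = 4.0,
                             base_rate: float = 0.05,
                             rng: np.random.Generator | None = None):
    """Background, one member set, and an annotation map with planted terms.

    Half the terms are enriched in the member set at ``fold`` times the
    background rate; returns (background set, member set, annotation
    frame, planted term ids).
    """
    rng = rng or np.random.default_rng(0)
    genes = np.array([f"G{i:05d}" for i in range(n_background)])
    members = set(rng.choice(genes, size=set_size, replace=False))
    in_set = np.array([g in members for g in genes])
    records, planted = [], set()
    for t in range(n_terms):
        term = f"T{t + 1:03d}"
        rate = np.full(n_background, base_rate)
        if t < n_terms // 2:
            rate[in_set] = min(1.0, fold * base_rate)
            planted.add(term)
        has = rng.random(n_background) < rate
        records.extend({"gene_id": g, "term_id": term} for g in genes[has])
    return set(genes), members, pd.DataFrame(records, columns=["gene_id", "term_id"]), planted


# ---------------------------------------------------------------------------
# on-disk layout

def write_dataset(ds: SyntheticDataset, outdir) -> list:
    """Write all dataset TSVs to a directory; returns the paths."""
    import pathlib

    from .containers import write_tsv, write_matrix

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    def _save(df, name, index=False):
        p = outdir / name
        write_tsv(df, p, index=index)
        paths.append(p)

    write_matrix(ds.counts, outdir / "counts.tsv")
    paths.append(outdir / "counts.tsv")
    _save(ds.lengths.to_frame(), "lengths.tsv", index=True)
    _save(ds.counts.samples, "samples.tsv", index=True)
    _save(ds.triads.reset_index(), "triads.tsv")
    _save(ds.tf_families, "tf_families.tsv")
    _save(ds.pathways, "pathways.tsv")
    _save(ds.truth.category, "truth_category.tsv")
    _save(ds.truth.cluster.to_frame(), "truth_cluster.tsv", index=True)
    _save(ds.truth.de, "truth_de.tsv")
    _save(ds.truth.enriched_terms, "truth_enriched.tsv")
    fp = ds.truth.planted_fpkm.copy()
    fp.index.name = "gene_id"
    _save(fp, "truth_fpkm.tsv", index=True)
    return paths
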