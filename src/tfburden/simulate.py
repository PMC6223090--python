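"""Synthetic inputs with the statistical structure the analysis assumes.

One master seed drives a random genome, multi-patient binding sites whose
per-donor inclusion probability grows with binding intensity (so sharing and
intensity are correlated), somatic mutations drawn from a 96-class
trinucleotide signature with a planted core enrichment, chromatin loops and
TADs coupled to gene expression, and read pileups with planted variant
alleles. Every emitted file parses through the package's own readers, and a
ground-truth sidecar records the planted quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSequence
from .genes import GeneTable
from .intervals import GenomicInterval
from .mutations import MutationTable
from .rates import CLASS_LABELS, N_CLASSES, N_TRINUCS, _CLASS_TO_TRINUC, BASES
from .topology import LoopSet, TADSet

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def default_signature(apobec_weight: float = 0.6) -> np.ndarray:
    """96-class signature with APOBEC-like mass on T[C>G]N and T[C>T]N,
    remainder uniform."""
    probs = np.full(N_CLASSES, (1 - apobec_weight) / N_CLASSES)
    apobec = [
        i
        for i, lab in enumerate(CLASS_LABELS)
        if lab[0] == "T" and lab[2] == "C" and lab[4] in "GT"
    ]
    probs[apobec] += apobec_weight / len(apobec)
    return probs / probs.sum()


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study conditions emulated.

    Rates are cohort-total mutations per bp; core_enrichment is the
    cohort-level core-vs-background rate ratio (per-site planted factors are
    modulated by intensity and outcome but normalized so their mean equals
    this value).
    """

    genome_length: int = 10_600_000
    n_chroms: int = 1
    gc_content: float = 0.41
    n_sites: int = 5000
    site_width: int = 400
    intensity_mu: float = 1.0
    intensity_sigma: float = 0.5
    n_donors: int = 50
    sharing_a: float = -3.0  # logistic intercept of per-donor inclusion
    sharing_b: float = 1.0  # slope on standardized log intensity
    background_rate: float = 5e-3  # SNVs per bp, cohort total
    core_enrichment: float = 1.25
    core_halfwidth: int = 200
    intensity_coupled_enrichment: bool = True
    sharing_burden_coef: float = 0.15  # direct sharing effect on core burden
    outcome_factor: float = 1.5  # relative burden of poor/met sites
    frac_good: float = 0.12
    frac_poor_met: float = 0.24
    frac_core: float = 0.10
    indel_rate: float = 4e-4  # indels per bp, cohort total
    indel_core_factor: float = 0.8  # < 1: cores protected from indels
    frac_blood_control: float = 0.107
    frac_adjacent_control: float = 0.018
    signature: np.ndarray = field(default_factory=default_signature)
    # topology / expression
    n_genes: int = 2000
    gene_length_range: tuple[int, int] = (1_000, 3_000)
    tad_size_range: tuple[int, int] = (300_000, 700_000)
    contact_a: float = -0.5
    contact_b: float = 0.5  # coefficient on log intensity
    contact_c: float = 0.2  # coefficient on core mutation count
    contact_dispersion: float = 0.5  # NB alpha
    loop_distal_min: int = 60_000
    expression_mu: float = 2.0
    expression_sigma: float = 0.5
    expression_shift: float = 1.0  # log shift for loop targets of >=3-mut sites
    # pileups
    pileup_depth: float = 30.0
    pileup_alt_fraction: float = 0.35
    variant_rate_good: float = 0.10
    variant_rate_poor: float = 0.25
    max_pileup_positions: int = 5000
    seed: int = 0

    def __post_init__(self):
        self.signature = np.asarray(self.signature, dtype=float)
        if not np.isclose(self.signature.sum(), 1.0):
            raise ValueError("signature must sum to 1")
        if self.core_enrichment < 0:
            raise ValueError("core_enrichment must be >= 0")


@dataclass
class SimTruth:
    sites: pd.DataFrame  # site_id, chrom, summit, intensity, sharing_count,
    #                      outcome, planted_core_factor, n_core_snvs, contact_count
    shifted_genes: list = field(default_factory=list)
    pileup: pd.DataFrame | None = None
    donors: pd.DataFrame | None = None


# ---------------------------------------------------------------------------


def simulate_genome(config: SimConfig, rng=None) -> GenomeSequence:
    """I.i.d. random genome at the configured GC content."""
    if config.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    per_chrom = config.genome_length // config.n_chroms
    byte_map = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    seqs = {}
    for i in range(config.n_chroms):
        codes = rng.choice(4, size=per_chrom, p=probs)
        seqs[f"chr{i + 1}"] = byte_map[codes].tobytes().decode("ascii")
    return GenomeSequence(seqs)


def _genome_trinuc_positions(genome: GenomeSequence):
    """Per chromosome: collapsed trinuc code per position (edge = -1) and,
    genome-wide, the 0-based positions hosting each of the 32 trinucs."""
    codes_by_chrom = {}
    pools: dict[int, list] = {t: [] for t in range(N_TRINUCS)}
    for chrom in genome.chroms:
        codes = genome.base_codes(chrom)
        left, center, right = codes[:-2], codes[1:-1], codes[2:]
        purine = (center == 0) | (center == 2)
        l2 = np.where(purine, 3 - right, left)
        r2 = np.where(purine, 3 - left, right)
        c2 = np.where(purine, 3 - center, center)
        valid = (left >= 0) & (center >= 0) & (right >= 0)
        cidx = np.where(c2 == 1, 0, 1)
        tri = np.where(valid, cidx * 16 + l2 * 4 + r2, -1)
        full = np.full(len(codes), -1, dtype=np.int64)
        full[1:-1] = tri
        codes_by_chrom[chrom] = full
        for t in range(N_TRINUCS):
            pos = np.flatnonzero(full == t)
            if len(pos):
                pools[t].append((chrom, pos))
    return codes_by_chrom, pools


def _alt_base_for_class(class_idx: int, genome_base: str) -> tuple[str, str]:
    """(ref, alt) on the genome strand for a pyrimidine-centered class placed
    at a position whose actual center base is ``genome_base``."""
    lab = CLASS_LABELS[class_idx]
    ref_collapsed, alt_collapsed = lab[2], lab[4]
    if genome_base == ref_collapsed:
        return genome_base, alt_collapsed
    return genome_base, _COMP[alt_collapsed]


def genome_context_cache(genome: GenomeSequence):
    """Precompute the per-chromosome trinucleotide codes and pools once so
    repeated mutation draws on one genome skip the scan."""
    return _genome_trinuc_positions(genome)


def simulate_sites_and_mutations(config: SimConfig, genome: GenomeSequence,
                                 rng=None, context_cache=None):
    """Binding sites with intensity/sharing/outcome labels plus a somatic
    mutation catalog with a planted core enrichment.

    Returns (sites, mutations, truth): ``sites`` is a list of intervals with
    summits and intensity scores, ``mutations`` a MutationTable, ``truth`` a
    SimTruth with the planted per-site factors.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = config.n_sites
    margin = 6000
    per_chrom_len = config.genome_length // config.n_chroms
    avail = per_chrom_len - 2 * margin
    chrom_names = genome.chroms
    counts = [n // len(chrom_names)] * len(chrom_names)
    counts[-1] += n - sum(counts)
    step_min = 2 * 1000 + 100
    sites: list[GenomicInterval] = []
    summits_by_chrom = {}
    idx = 0
    for chrom, n_c in zip(chrom_names, counts):
        if n_c == 0:
            continue
        step = avail / n_c
        if step < step_min:
            raise ValueError(
                f"cannot place {n_c} non-overlapping 1 kb windows on {chrom}"
            )
        jitter = rng.uniform(-0.2, 0.2, size=n_c) * (step - step_min)
        summits = (margin + (np.arange(n_c) + 0.5) * step + jitter).astype(np.int64)
        summits_by_chrom[chrom] = summits
        half = config.site_width // 2
        for s in summits:
            sites.append(
                GenomicInterval(
                    chrom=chrom, start=int(s) - half, end=int(s) + half,
                    name=f"site_{idx:05d}", summit=int(s) + 1,
                )
            )
            idx += 1

    intensity = rng.lognormal(config.intensity_mu, config.intensity_sigma, size=n)
    for site, inten in zip(sites, intensity):
        site.score = float(inten)

    z = (np.log(intensity) - np.log(intensity).mean()) / np.log(intensity).std()
    p_incl = 1.0 / (1.0 + np.exp(-(config.sharing_a + config.sharing_b * z)))
    p_incl = np.clip(p_incl, 0.02, 0.98)
    membership = rng.random((n, config.n_donors)) < p_incl[:, None]
    lonely = ~membership.any(axis=1)
    membership[lonely, rng.integers(0, config.n_donors, size=lonely.sum())] = True
    sharing = membership.sum(axis=1)

    outcome = np.array(["none"] * n, dtype=object)
    order = rng.permutation(n)
    n_good = int(round(config.frac_good * n))
    n_poor = int(round(config.frac_poor_met * n))
    n_core = int(round(config.frac_core * n))
    outcome[order[:n_good]] = "good"
    outcome[order[n_good : n_good + n_poor]] = "poor_met"
    outcome[order[n_good + n_poor : n_good + n_poor + n_core]] = "core"

    # planted per-site core factors, normalized to mean = core_enrichment;
    # modulated by intensity, a direct sharing effect, and outcome class
    w = intensity / intensity.mean() if config.intensity_coupled_enrichment else np.ones(n)
    z_sh = (sharing - sharing.mean()) / max(sharing.std(), 1e-9)
    u = (w
         * np.exp(config.sharing_burden_coef * z_sh)
         * np.where(outcome == "poor_met", config.outcome_factor, 1.0))
    u = u / u.mean()
    factors = 1.0 + (config.core_enrichment - 1.0) * u

    donor_ids = np.array([f"D{i:03d}" for i in range(config.n_donors)], dtype=object)
    tissue = np.array(["unknown"] * config.n_donors, dtype=object)
    n_blood = int(round(config.frac_blood_control * config.n_donors))
    n_adj = int(round(config.frac_adjacent_control * config.n_donors))
    dorder = rng.permutation(config.n_donors)
    tissue[dorder[:n_blood]] = "blood"
    tissue[dorder[n_blood : n_blood + n_adj]] = "adjacent"

    if context_cache is None:
        context_cache = _genome_trinuc_positions(genome)
    codes_by_chrom, pools = context_cache
    pool_arrays = {}
    for t, chunks in pools.items():
        if chunks:
            pool_arrays[t] = chunks  # list of (chrom, positions)

    rows = []  # chrom, pos(1-based), ref, alt, donor_idx, mut_type

    # background SNVs, context-respecting (vectorized per class and chrom)
    total_len = sum(genome.chrom_length(c) for c in genome.chroms)
    n_bg = rng.poisson(config.background_rate * total_len)
    class_counts = rng.multinomial(n_bg, config.signature)
    base_codes = {c: genome.base_codes(c) for c in genome.chroms}
    bg_chrom, bg_pos, bg_ref, bg_alt = [], [], [], []
    for ci in range(N_CLASSES):
        k = int(class_counts[ci])
        if k == 0:
            continue
        t = int(_CLASS_TO_TRINUC[ci])
        chunks = pool_arrays.get(t)
        if not chunks:
            raise ValueError(
                f"signature places mass on {CLASS_LABELS[ci]} but no genome "
                f"position has the matching context"
            )
        lab = CLASS_LABELS[ci]
        ref_pyr, alt_pyr = lab[2], lab[4]
        ref_pur, alt_pur = _COMP[ref_pyr], _COMP[alt_pyr]
        sizes = np.array([len(p) for _, p in chunks], dtype=float)
        per_chunk = rng.multinomial(k, sizes / sizes.sum())
        for (chrom, pos_arr), kc in zip(chunks, per_chunk):
            if kc == 0:
                continue
            pos0 = pos_arr[rng.integers(0, len(pos_arr), size=kc)]
            pyr = (base_codes[chrom][pos0] == 1) | (base_codes[chrom][pos0] == 3)
            bg_chrom.append(np.full(kc, chrom, dtype=object))
            bg_pos.append(pos0 + 1)
            bg_ref.append(np.where(pyr, ref_pyr, ref_pur))
            bg_alt.append(np.where(pyr, alt_pyr, alt_pur))
    if bg_chrom:
        n_total_bg = sum(len(a) for a in bg_pos)
        bg_df = pd.DataFrame(
            {
                "chrom": np.concatenate(bg_chrom),
                "pos": np.concatenate(bg_pos),
                "ref": np.concatenate(bg_ref).astype(object),
                "alt": np.concatenate(bg_alt).astype(object),
                "donor_idx": rng.integers(0, config.n_donors, size=n_total_bg),
                "mut_type": "SNV",
            }
        )
    else:
        bg_df = pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "donor_idx", "mut_type"]
        )

    # planted core enrichment: extra SNVs within ±core_halfwidth of summits
    hw = config.core_halfwidth
    sig_by_trinuc = np.zeros(N_TRINUCS)
    for ci in range(N_CLASSES):
        sig_by_trinuc[_CLASS_TO_TRINUC[ci]] += config.signature[ci]
    classes_of_trinuc = {
        t: [ci for ci in range(N_CLASSES) if _CLASS_TO_TRINUC[ci] == t]
        for t in range(N_TRINUCS)
    }
    for si, site in enumerate(sites):
        lam = (factors[si] - 1.0) * config.background_rate * (2 * hw + 1)
        if lam <= 0:
            continue
        n_extra = rng.poisson(lam)
        if n_extra == 0:
            continue
        codes = codes_by_chrom[site.chrom]
        summit0 = site.summit - 1
        core_codes = codes[summit0 - hw : summit0 + hw + 1]
        avail_t = [t for t in range(N_TRINUCS) if (core_codes == t).any() and sig_by_trinuc[t] > 0]
        if not avail_t:
            raise ValueError(
                f"core of {site.name} has no position matching any signature context"
            )
        probs_t = np.array([sig_by_trinuc[t] for t in avail_t])
        probs_t /= probs_t.sum()
        members = np.flatnonzero(membership[si])
        for _ in range(n_extra):
            t = avail_t[rng.choice(len(avail_t), p=probs_t)]
            local = np.flatnonzero(core_codes == t)
            pos0 = summit0 - hw + int(local[rng.integers(0, len(local))])
            cls_pool = classes_of_trinuc[t]
            cls_probs = config.signature[cls_pool] / config.signature[cls_pool].sum()
            ci = int(rng.choice(cls_pool, p=cls_probs))
            base = genome.fetch(site.chrom, pos0, pos0 + 1)
            ref, alt = _alt_base_for_class(ci, base)
            donor = int(members[rng.integers(0, len(members))])
            rows.append((site.chrom, pos0 + 1, ref, alt, donor, "SNV"))

    # indels: uniform background, thinned inside cores when protective
    n_indel = rng.poisson(config.indel_rate * total_len)
    all_summits = {c: np.sort(s) for c, s in summits_by_chrom.items()}
    chrom_lengths = {c: genome.chrom_length(c) for c in genome.chroms}
    chrom_probs = np.array([chrom_lengths[c] for c in genome.chroms], dtype=float)
    chrom_probs /= chrom_probs.sum()
    for _ in range(n_indel):
        chrom = genome.chroms[rng.choice(len(genome.chroms), p=chrom_probs)]
        pos0 = int(rng.integers(10, chrom_lengths[chrom] - 10))
        summits = all_summits.get(chrom)
        if summits is not None and len(summits):
            j = np.searchsorted(summits, pos0)
            near = min(
                abs(pos0 - summits[max(j - 1, 0)]),
                abs(pos0 - summits[min(j, len(summits) - 1)]),
            )
            if near <= hw and rng.random() > config.indel_core_factor:
                continue
        length = int(rng.integers(1, 4))
        anchor = genome.fetch(chrom, pos0, pos0 + 1)
        if rng.random() < 0.5:  # insertion
            ins = "".join(rng.choice(list("ACGT"), size=length))
            rows.append((chrom, pos0 + 1, anchor, anchor + ins,
                         rng.integers(0, config.n_donors), "INS"))
        else:
            deleted = genome.fetch(chrom, pos0, pos0 + 1 + length)
            rows.append((chrom, pos0 + 1, deleted, anchor,
                         rng.integers(0, config.n_donors), "DEL"))

    mut_df = pd.concat(
        [
            bg_df,
            pd.DataFrame(
                rows, columns=["chrom", "pos", "ref", "alt", "donor_idx", "mut_type"]
            ),
        ],
        ignore_index=True,
    )
    mut_df["donor_id"] = donor_ids[mut_df["donor_idx"].to_numpy(dtype=np.int64)]
    mut_df["control_tissue"] = tissue[mut_df["donor_idx"].to_numpy(dtype=np.int64)]
    mut_df = mut_df.drop(columns="donor_idx")
    mut_df = mut_df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    mutations = MutationTable(mut_df)

    # realized core SNV counts per site (planted + background)
    n_core = np.zeros(n, dtype=np.int64)
    snv = mut_df[mut_df["mut_type"] == "SNV"]
    for chrom, grp in snv.groupby("chrom"):
        summits = summits_by_chrom.get(chrom)
        if summits is None:
            continue
        order = np.argsort(summits)
        ssorted = summits[order]
        pos0 = grp["pos"].to_numpy() - 1
        j = np.searchsorted(ssorted, pos0)
        c1 = np.clip(j - 1, 0, len(ssorted) - 1)
        c2 = np.clip(j, 0, len(ssorted) - 1)
        hit1 = np.abs(pos0 - ssorted[c1]) <= hw
        hit2 = (np.abs(pos0 - ssorted[c2]) <= hw) & (c2 != c1)
        np.add.at(n_core, _site_index_lookup(chrom, c1[hit1], order, chrom_names, counts), 1)
        np.add.at(n_core, _site_index_lookup(chrom, c2[hit2], order, chrom_names, counts), 1)

    truth_sites = pd.DataFrame(
        {
            "site_id": [s.name for s in sites],
            "chrom": [s.chrom for s in sites],
            "summit": [s.summit for s in sites],
            "intensity": intensity,
            "sharing_count": sharing,
            "outcome": outcome,
            "planted_core_factor": factors,
            "n_core_snvs": n_core,
        }
    )
    donors_df = pd.DataFrame({"donor_id": donor_ids, "control_tissue": tissue})
    truth = SimTruth(sites=truth_sites, donors=donors_df)
    truth.membership = membership
    return sites, mutations, truth


def _site_index_lookup(chrom, local_indices, order, chrom_names, counts):
    base = 0
    for c, n_c in zip(chrom_names, counts):
        if c == chrom:
            return base + order[local_indices]
        base += n_c
    raise KeyError(chrom)


# ---------------------------------------------------------------------------


def simulate_topology_expression(config: SimConfig, sites, truth: SimTruth,
                                 genome: GenomeSequence, rng=None):
    """Loops, TADs, and a gene table coupled to the planted mutation burden.

    Contact counts are NB with log-mean linear in log intensity and core
    mutation count; loops connect each site to distal genes (> loop_distal_min
    away) within its TAD; loop targets of sites with >= 3 core mutations get
    an expression shift. Linearly proximal genes receive no shift of their own.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    lo_sz, hi_sz = config.tad_size_range
    tad_ivs = []
    for chrom in genome.chroms:
        length = genome.chrom_length(chrom)
        pos = 0
        while pos < length:
            size = int(rng.integers(lo_sz, hi_sz + 1))
            tad_ivs.append(GenomicInterval(chrom, pos, min(pos + size, length)))
            pos += size
    tads = TADSet(tad_ivs)

    chrom_lengths = {c: genome.chrom_length(c) for c in genome.chroms}
    chrom_probs = np.array([chrom_lengths[c] for c in genome.chroms], dtype=float)
    chrom_probs /= chrom_probs.sum()
    gene_rows = []
    for gi in range(config.n_genes):
        chrom = genome.chroms[rng.choice(len(genome.chroms), p=chrom_probs)]
        length = int(rng.integers(*config.gene_length_range))
        start = int(rng.integers(1_000, chrom_lengths[chrom] - length - 1_000))
        strand = "+" if rng.random() < 0.5 else "-"
        expr = float(rng.lognormal(config.expression_mu, config.expression_sigma))
        gene_rows.append((f"gene_{gi:05d}", chrom, start, start + length, strand, expr))
    genes_df = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end",
                                                "strand", "expression"])

    st = truth.sites
    mu = np.exp(
        config.contact_a
        + config.contact_b * np.log(st["intensity"].to_numpy())
        + config.contact_c * st["n_core_snvs"].to_numpy()
    )
    alpha = config.contact_dispersion
    if alpha > 0:
        lam = rng.gamma(shape=1 / alpha, scale=mu * alpha)
    else:
        lam = mu
    contact = rng.poisson(lam)

    tss = np.where(genes_df["strand"] == "-", genes_df["end"] - 1, genes_df["start"])
    genes_df = genes_df.assign(tss=tss)
    loop_rows = []
    shifted: set[str] = set()
    realized = np.zeros(len(sites), dtype=np.int64)
    n_core_snvs = st["n_core_snvs"].to_numpy()
    for si, site in enumerate(sites):
        k = int(contact[si])
        if k == 0:
            continue
        summit0 = site.summit - 1
        tad = tads.containing(site.chrom, summit0)
        if tad is None:
            continue
        in_tad = genes_df[
            (genes_df["chrom"] == site.chrom)
            & (genes_df["start"] < tad.end)
            & (genes_df["end"] > tad.start)
        ]
        if len(in_tad) == 0:
            continue
        dist = np.abs(in_tad["tss"].to_numpy() - summit0)
        distal = in_tad[dist > config.loop_distal_min]
        pool = distal if len(distal) else in_tad
        # k distinct target genes (capped by the pool); anchors are kept
        # narrow — summit ± 100 bp and TSS ± 500 bp — so realized loop counts
        # round-trip through anchor-overlap counting
        picks = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        realized[si] = len(picks)
        for p in picks:
            g = pool.iloc[int(p)]
            loop_rows.append(
                (site.chrom, max(summit0 - 100, 0), summit0 + 100, g["chrom"],
                 max(int(g["tss"]) - 500, 0), int(g["tss"]) + 500, 1.0)
            )
            if n_core_snvs[si] >= 3:
                shifted.add(g["gene_id"])
    truth.sites = st.assign(contact_count=realized)
    if config.expression_shift != 0 and shifted:
        sel = genes_df["gene_id"].isin(shifted)
        genes_df.loc[sel, "expression"] *= np.exp(config.expression_shift)
    truth.shifted_genes = sorted(shifted)
    loops = LoopSet(
        pd.DataFrame(
            loop_rows,
            columns=["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
                     "weight"],
        )
    )
    genes = GeneTable(genes_df.drop(columns="tss"))
    return loops, tads, genes


# ---------------------------------------------------------------------------


def simulate_pileups(config: SimConfig, truth: SimTruth, mutations: MutationTable,
                     rng=None):
    """Per-outcome-group read pileups with planted variant alleles at somatic
    positions near outcome-labeled summits.

    Returns (pileups, candidates, pileup_truth): ``pileups`` maps group label
    to a pileup DataFrame; ``candidates`` maps (chrom, pos) to (ref, alt);
    ``pileup_truth`` records depth and planted alt counts per position.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    st = truth.sites
    hw = config.core_halfwidth
    snv = mutations.snvs.df
    groups = {"good": "good", "poor_met": "poor_met"}
    variant_rate = {"good": config.variant_rate_good,
                    "poor_met": config.variant_rate_poor}
    pileups: dict[str, pd.DataFrame] = {}
    candidates: dict[tuple, tuple] = {}
    truth_rows = []
    site_of_position: dict[tuple, str] = {}
    for label, outcome in groups.items():
        sub_sites = st[st["outcome"] == outcome]
        cand, seen = [], set()
        for row in sub_sites.itertuples(index=False):
            near = snv[
                (snv["chrom"] == row.chrom)
                & (snv["pos"] - 1 >= row.summit - 1 - hw)
                & (snv["pos"] - 1 <= row.summit - 1 + hw)
            ]
            for m in near.itertuples(index=False):
                if (m.chrom, int(m.pos)) in seen:  # recurrent catalog entries
                    continue
                seen.add((m.chrom, int(m.pos)))
                cand.append((m.chrom, int(m.pos), m.ref, m.alt, row.site_id))
        cand = cand[: config.max_pileup_positions]
        rows = []
        for chrom, pos, ref, alt, site_id in cand:
            candidates[(chrom, pos)] = (ref, alt)
            site_of_position[(chrom, pos)] = site_id
            depth = int(rng.poisson(config.pileup_depth))
            present = rng.random() < variant_rate[label]
            n_alt = int(rng.binomial(depth, config.pileup_alt_fraction)) if present else 0
            n_alt = min(n_alt, depth)
            for _ in range(n_alt):
                rows.append((chrom, pos, alt, 37, 60, f"{label}_merged"))
            for _ in range(depth - n_alt):
                rows.append((chrom, pos, ref, 37, 60, f"{label}_merged"))
            truth_rows.append((label, site_id, chrom, pos, ref, alt, depth,
                               n_alt, present))
        pileups[label] = pd.DataFrame(
            rows, columns=["chrom", "pos", "base", "baseq", "mapq", "sample"]
        )
    truth.pileup = pd.DataFrame(
        truth_rows,
        columns=["group", "site_id", "chrom", "pos", "ref", "alt", "depth",
                 "alt_count", "variant_present"],
    )
    truth.site_of_position = site_of_position
    return pileups, candidates, truth.pileup


# ---------------------------------------------------------------------------


def simulate_all(config: SimConfig, outdir):
    """Generate every input the pipeline reads and write it under one
    directory; returns the in-memory objects as well."""
    import os

    from .intervals import write_interval_file
    from .mutations import write_mutation_table

    os.makedirs(outdir, exist_ok=True)
    rng_master = np.random.SeedSequence(config.seed)
    seeds = rng_master.spawn(4)
    genome = simulate_genome(config, np.random.default_rng(seeds[0]))
    sites, mutations, truth = simulate_sites_and_mutations(
        config, genome, np.random.default_rng(seeds[1])
    )
    loops, tads, genes = simulate_topology_expression(
        config, sites, truth, genome, np.random.default_rng(seeds[2])
    )
    pileups, candidates, pileup_truth = simulate_pileups(
        config, truth, mutations, np.random.default_rng(seeds[3])
    )

    genome.write_fasta(os.path.join(outdir, "genome.fa"))
    import pyfaidx

    pyfaidx.Faidx(os.path.join(outdir, "genome.fa"))  # build the .fai index
    write_interval_file(sites, os.path.join(outdir, "peaks.narrowPeak"), "narrowPeak")
    summit_ivs = [
        GenomicInterval(s.chrom, s.summit - 1, s.summit, name=s.name) for s in sites
    ]
    write_interval_file(summit_ivs, os.path.join(outdir, "summits.bed"), "bed6")
    write_mutation_table(mutations, os.path.join(outdir, "mutations.tsv"))
    loops.write_bedpe(os.path.join(outdir, "loops.bedpe"))
    tad_rows = [iv for ivs in tads.by_chrom.values() for iv in ivs]
    write_interval_file(tad_rows, os.path.join(outdir, "tads.bed"), "bed3")
    genes.write_tsv(os.path.join(outdir, "genes.tsv"))
    for label, df in pileups.items():
        df.to_csv(os.path.join(outdir, f"pileup_{label}.tsv"), sep="\t", index=False)
    cand_df = pd.DataFrame(
        [(c, p, r, a) for (c, p), (r, a) in sorted(candidates.items())],
        columns=["chrom", "pos", "ref", "alt"],
    )
    cand_df.to_csv(os.path.join(outdir, "candidate_positions.tsv"), sep="\t", index=False)
    truth.sites.to_csv(os.path.join(outdir, "truth_sites.tsv"), sep="\t", index=False)
    if truth.pileup is not None:
        truth.pileup.to_csv(os.path.join(outdir, "truth_pileup.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "truth.txt"), "w") as fh:
        fh.write(f"seed\t{config.seed}\n")
        fh.write(f"core_enrichment\t{config.core_enrichment}\n")
        fh.write(f"background_rate\t{config.background_rate}\n")
        fh.write(f"expression_shift\t{config.expression_shift}\n")
        fh.write(f"n_shifted_genes\t{len(truth.shifted_genes)}\n")
    return {
        "genome": genome, "sites": sites, "mutations": mutations, "truth": truth,
        "loops": loops, "tads": tads, "genes": genes, "pileups": pileups,
        "candidates": candidates,
    }
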