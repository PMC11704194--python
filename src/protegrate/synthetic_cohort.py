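"""Synthetic multi-omics cohort generator with known ground truth.

Emulates the data a proteogenomic tumor study consumes — copy-number
segments, somatic mutations with trinucleotide contexts, mRNA /
protein / phosphosite abundance matrices, a peptide-level intensity
table and a survival table — while planting the statistical structure
the downstream stages are meant to recover: arm-level losses and focal
amplifications, copy-number dosage (cis) effects, cluster-specific
expression programs, kinase-driven substrate shifts, mutational
signature mixtures, and survival hazards tied to the planted cluster
labels.

Abundances are generated on the log2 scale and exponentiated to
positive FOT-like values for output.  One integer seed drives a fixed
set of named substreams (clusters, segments, expression, phospho,
mutations, survival, peptides), so adding a stream never perturbs the
others and a fixed seed reproduces the cohort bit-identically.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from protegrate import io
from protegrate.cnv_genomics import CONTEXTS_96, SUBSTITUTIONS, gene_copy_number
from protegrate.core import OmicsMatrix

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: genome layout: 4 chromosomes, 8 arms, 1-based inclusive coordinates
_CHROM_LENGTH = 200_000_000
_CENTROMERE = 90_000_000
_ARMS = [f"{c}{a}" for c in ("1", "2", "3", "4") for a in ("p", "q")]

#: substream names, fixed order; indices into SeedSequence.spawn
_STREAMS = ("clusters", "segments", "expression", "phospho", "mutations", "survival", "peptides")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def gene_model(n_genes: int) -> pd.DataFrame:
    """Deterministic gene model: genes in contiguous blocks over 8 arms."""
    rows = []
    per_arm = int(np.ceil(n_genes / len(_ARMS)))
    for i in range(n_genes):
        arm = _ARMS[min(i // per_arm, len(_ARMS) - 1)]
        chrom, pq = arm[0], arm[1]
        j = i % per_arm
        lo, hi = (1, _CENTROMERE) if pq == "p" else (_CENTROMERE + 1, _CHROM_LENGTH)
        span = (hi - lo) // per_arm
        start = lo + j * span + 1000
        rows.append(dict(gene=f"G{i + 1:04d}", chrom=chrom, start=start,
                         end=start + 50_000, arm=arm))
    return pd.DataFrame(rows)


def reference_signatures() -> pd.DataFrame:
    """Two synthetic, well-separated 96-context mutational signatures.

    SynSigA concentrates on C>T substitutions (clock-like flavor),
    SynSigB on C>A; both keep a small uniform floor over all 96
    contexts.  These are synthetic stand-ins constructed for testing;
    they are not COSMIC profiles.
    """
    profiles = {}
    for name, sub, peak3 in (("SynSigA", "C>T", "G"), ("SynSigB", "C>A", "A")):
        w = np.full(96, 0.1 / 96)
        for i, ctx in enumerate(CONTEXTS_96):
            if f"[{sub}]" in ctx:
                w[i] += 0.9 / 32
                if ctx.endswith(peak3):  # peak at a preferred 3' base
                    w[i] += 0.9 / 32
        profiles[name] = w / w.sum()
    return pd.DataFrame(profiles, index=pd.Index(CONTEXTS_96, name="context"))


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort and its planted effects.

    Fractions, shifts and slopes are on the log2-ratio / log2-abundance
    scale.  ``cluster_spec`` fractions must sum to <= 1 (remaining
    samples form a 'background' cluster); ``signature_mix`` weights sum
    to 1 over the reference signature columns.
    """

    n_samples: int = 200
    n_genes: int = 2000
    arm_events: list = field(default_factory=list)  # (arm, fraction, mean log2 shift)
    focal_events: list = field(default_factory=list)  # (label, [genes], fraction, shift)
    cis_genes: list = field(default_factory=list)  # (gene, dosage slope)
    cluster_spec: list = field(default_factory=list)  # (label, fraction, [program genes], shift)
    kinase_spec: list = field(default_factory=list)  # (kinase, [site ids], {cluster: activity shift})
    signature_mix: tuple = (0.6, 0.4)
    survival_spec: dict = field(default_factory=lambda: {"baseline_hazard": 0.02, "hazard_ratios": {}})
    noise_sd: float = 0.5
    seed: int = 0
    # secondary knobs
    segment_noise_sd: float = 0.1
    mean_mutations: float = 316.0
    coding_mb: float = 31.6
    indel_fraction: float = 0.05
    signature_concentration: float = 8.0
    n_background_sites: int = 100
    missing_rate: float = 0.0
    censor_tmax: float = 120.0  # months of administrative censoring

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise ValueError("n_samples and n_genes must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if abs(sum(self.signature_mix) - 1.0) > 1e-9:
            raise ValueError("signature_mix weights must sum to 1")
        frac = sum(f for _, f, *_ in self.cluster_spec)
        if frac > 1 + 1e-9:
            raise ValueError(f"cluster fractions sum to {frac:.3f} > 1")
        genes = set(gene_model(self.n_genes)["gene"])
        seen: dict[str, str] = {}
        for label, members, _, _ in self.focal_events:
            for g in members:
                if g not in genes:
                    raise ValueError(f"focal event {label!r}: unknown gene {g}")
                if g in seen:
                    raise ValueError(
                        f"overlapping focal loci: gene {g} in both {seen[g]!r} and {label!r}"
                    )
                seen[g] = label
        for g, _ in self.cis_genes:
            if g not in genes:
                raise ValueError(f"cis gene {g} not in the gene universe")


def default_cohort_spec(n_samples: int = 200, n_genes: int = 2000, seed: int = 0,
                        noise_sd: float = 0.5) -> CohortSpec:
    """The reference cohort scenario: one arm loss, one focal gain,
    dosage-coupled cis genes on the lost arm, three cluster programs,
    three kinases each driving ten substrate sites in one cluster, a
    two-signature mutation mixture, and a hazard increase in cluster C3.
    """
    gm = gene_model(n_genes)
    arm4q = gm.loc[gm["arm"] == "4q", "gene"].tolist()
    arm2p = gm.loc[gm["arm"] == "2p", "gene"].tolist()
    cis = [(g, 1.5) for g in arm4q[:20]]
    focal_genes = arm2p[:5]
    pool = [g for g in gm["gene"] if g not in set(arm4q[:20]) | set(focal_genes)]
    # program and substrate-set sizes scale down gracefully on small genomes
    prog_size = max(5, min(40, len(pool) // 6))
    programs = [pool[i * prog_size:(i + 1) * prog_size] for i in range(3)]
    clusters = [(f"C{i + 1}", 1 / 3, programs[i], 1.0) for i in range(3)]
    kin_sub_pool = pool[3 * prog_size:]
    n_sub = max(3, min(10, len(kin_sub_pool) // 3))
    kinases = []
    for i in range(3):
        sites = [f"{p}_S{10 * (j + 1)}"
                 for j, p in enumerate(kin_sub_pool[i * n_sub:(i + 1) * n_sub])]
        kinases.append((f"KIN{i + 1}", sites, {f"C{i + 1}": 1.0}))
    return CohortSpec(
        n_samples=n_samples,
        n_genes=n_genes,
        arm_events=[("4q", 0.5, -1.0)],
        focal_events=[("2p_amp", focal_genes, 0.25, 1.5)],
        cis_genes=cis,
        cluster_spec=clusters,
        kinase_spec=kinases,
        signature_mix=(0.6, 0.4),
        survival_spec={"baseline_hazard": 0.02, "hazard_ratios": {"C3": 2.5}},
        noise_sd=noise_sd,
        seed=seed,
    )


@dataclass
class GroundTruth:
    cluster_labels: pd.Series  # per-sample planted cluster
    arm_carriers: pd.DataFrame  # samples x arm-event bool
    focal_carriers: pd.DataFrame  # samples x focal-event bool
    cis_genes: list  # (gene, slope)
    kinase_activity: pd.DataFrame  # kinases x samples true activity
    signature_exposures: pd.DataFrame  # samples x signatures mixture weights
    hazards: pd.Series  # per-sample hazard rate


@dataclass
class Cohort:
    segments: pd.DataFrame
    mutations: pd.DataFrame
    mrna: OmicsMatrix
    protein: OmicsMatrix
    phospho: OmicsMatrix
    peptides: pd.DataFrame
    survival: pd.DataFrame
    truth: GroundTruth
    gene_model: pd.DataFrame
    gene_sets: dict
    ks_map: pd.DataFrame
    observable_counts: pd.Series


def _assign_clusters(spec: CohortSpec, samples: list[str], rng) -> pd.Series:
    labels = np.array(["background"] * spec.n_samples, dtype=object)
    order = rng.permutation(spec.n_samples)
    pos = 0
    for label, fraction, *_ in spec.cluster_spec:
        count = int(round(fraction * spec.n_samples))
        labels[order[pos:pos + count]] = label
        pos += count
    return pd.Series(labels, index=samples, name="cluster")


def _make_segments(spec: CohortSpec, samples, gm, arm_carriers, focal_carriers, rng):
    """Per sample and arm, non-overlapping segments with breakpoints at
    focal-event boundaries; carriers get the planted mean shift added."""
    arm_bounds = gm.groupby("arm").agg(chrom=("chrom", "first"),
                                       start=("start", "min"), end=("end", "max"))
    arm_shift = {arm: shift for arm, _, shift in spec.arm_events}
    focal_regions = []  # (label, arm, start, end, shift)
    for label, members, _, shift in spec.focal_events:
        sub = gm[gm["gene"].isin(members)]
        focal_regions.append((label, sub["arm"].iloc[0], int(sub["start"].min()),
                              int(sub["end"].max()), shift))
    rows = []
    for s_idx, sample in enumerate(samples):
        for arm, bounds in arm_bounds.iterrows():
            pieces = [(int(bounds["start"]), int(bounds["end"]), 0.0)]
            for label, farm, fs, fe, fshift in focal_regions:
                if farm != arm:
                    continue
                add = fshift if focal_carriers.loc[sample, label] else 0.0
                new = []
                for a, b, extra in pieces:
                    if fe < a or fs > b:
                        new.append((a, b, extra))
                        continue
                    if a < fs:
                        new.append((a, fs - 1, extra))
                    new.append((max(a, fs), min(b, fe), extra + add))
                    if b > fe:
                        new.append((fe + 1, b, extra))
                pieces = new
            base = arm_shift.get(arm, 0.0) if (
                arm in arm_carriers.columns and arm_carriers.loc[sample, arm]
            ) else 0.0
            for a, b, extra in pieces:
                mid = (a + b) // 2
                for lo, hi in ((a, mid), (mid + 1, b)):  # two segments per piece
                    if hi <= lo:
                        continue
                    log2 = base + extra + rng.normal(0.0, spec.segment_noise_sd)
                    rows.append(dict(sample=sample, chrom=bounds["chrom"], start=lo,
                                     end=hi, nmark=max(10, (hi - lo) // 100_000),
                                     log2=round(float(log2), 6)))
    return pd.DataFrame(rows)


def _expression_layer(spec, gm, samples, cn, clusters, rng, baseline):
    """log2 abundance = baseline + dosage + cluster program shift + noise."""
    n_g, n_s = len(gm), len(samples)
    X = np.tile(baseline[:, None], (1, n_s)) + rng.normal(0.0, spec.noise_sd, size=(n_g, n_s))
    gidx = {g: i for i, g in enumerate(gm["gene"])}
    sidx = {s: j for j, s in enumerate(samples)}
    cn_filled = cn.data.fillna(0.0)
    for gene, slope in spec.cis_genes:
        X[gidx[gene], :] += slope * cn_filled.loc[gene, samples].to_numpy()
    for label, _, program, shift in spec.cluster_spec:
        cols = [sidx[s] for s in samples if clusters[s] == label]
        for g in program:
            X[gidx[g], cols] += shift
    return pd.DataFrame(X, index=gm["gene"].to_numpy(), columns=samples)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full multi-omics cohort described by ``spec``.

    Deterministic under a fixed ``spec.seed``; see the module docstring
    for the generative model of each layer.
    """
    spec.validate()
    rngs = _rngs(spec.seed)
    samples = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    gm = gene_model(spec.n_genes)
    clusters = _assign_clusters(spec, samples, rngs["clusters"])

    seg_rng = rngs["segments"]
    arm_carriers = pd.DataFrame(
        {arm: seg_rng.random(spec.n_samples) < frac for arm, frac, _ in spec.arm_events},
        index=samples, dtype=bool,
    )
    focal_carriers = pd.DataFrame(
        {label: seg_rng.random(spec.n_samples) < frac
         for label, _, frac, _ in spec.focal_events},
        index=samples, dtype=bool,
    )
    segments = _make_segments(spec, samples, gm, arm_carriers, focal_carriers, seg_rng)
    cn = gene_copy_number(segments, gm)

    expr_rng = rngs["expression"]
    baseline = expr_rng.normal(5.0, 1.0, size=spec.n_genes)
    mrna_log2 = _expression_layer(spec, gm, samples, cn, clusters, expr_rng, baseline)
    prot_log2 = _expression_layer(spec, gm, samples, cn, clusters, expr_rng, baseline)

    # phosphosites: kinase substrate sites + one site per cis gene + background
    ph_rng = rngs["phospho"]
    kin_activity = pd.DataFrame(0.0, index=[k for k, _, _ in spec.kinase_spec], columns=samples)
    for kinase, _, shifts in spec.kinase_spec:
        for s in samples:
            kin_activity.loc[kinase, s] = shifts.get(clusters[s], 0.0) + ph_rng.normal(0.0, 0.1)
    site_rows, site_log2 = [], []
    prot_idx = {g: i for i, g in enumerate(gm["gene"])}
    cn_filled = cn.data.fillna(0.0)
    for kinase, sites, _ in spec.kinase_spec:
        for site in sites:
            b = ph_rng.normal(5.0, 1.0)
            vals = b + kin_activity.loc[kinase].to_numpy() + ph_rng.normal(
                0.0, spec.noise_sd, size=spec.n_samples)
            site_rows.append(site)
            site_log2.append(vals)
    for gene, slope in spec.cis_genes:
        site = f"{gene}_S1"
        vals = (baseline[prot_idx[gene]]
                + slope * cn_filled.loc[gene, samples].to_numpy()
                + ph_rng.normal(0.0, spec.noise_sd, size=spec.n_samples))
        site_rows.append(site)
        site_log2.append(vals)
    used = {s.split("_")[0] for s in site_rows}
    bg_proteins = [g for g in gm["gene"] if g not in used][:spec.n_background_sites]
    for g in bg_proteins:
        b = ph_rng.normal(5.0, 1.0)
        site_rows.append(f"{g}_S5")
        site_log2.append(b + ph_rng.normal(0.0, spec.noise_sd, size=spec.n_samples))
    phospho_log2 = pd.DataFrame(np.array(site_log2), index=site_rows, columns=samples)

    def to_linear(log2_df, rng):
        lin = np.power(2.0, log2_df)
        if spec.missing_rate > 0:
            mask = rng.random(lin.shape) < spec.missing_rate
            lin = lin.mask(mask)
        return lin

    mrna = OmicsMatrix(to_linear(mrna_log2, expr_rng), layer="mrna")
    protein = OmicsMatrix(to_linear(prot_log2, expr_rng), layer="protein")
    phospho = OmicsMatrix(to_linear(phospho_log2, ph_rng), layer="phospho")

    # peptide-level table for the quantification stage (first 50 proteins)
    pep_rng = rngs["peptides"]
    quant_proteins = gm["gene"].tolist()[:min(50, spec.n_genes)]
    obs_counts = pd.Series(
        {g: int(pep_rng.integers(5, 16)) for g in quant_proteins}, name="observable"
    )
    pep_rows = []
    for g in quant_proteins:
        n_pep = int(pep_rng.integers(3, 9))
        weights = pep_rng.dirichlet(np.ones(n_pep))
        for s in samples:
            abundance = protein.data.loc[g, s]
            if not np.isfinite(abundance):
                continue
            total = abundance * obs_counts[g]
            for j in range(n_pep):
                pep_rows.append(dict(sample=s, protein=g,
                                     peptide=f"{g}_PEP{j + 1}",
                                     intensity=float(total * weights[j])))
    peptides = pd.DataFrame(pep_rows)

    # mutations: per-sample exposures over the reference signatures
    mut_rng = rngs["mutations"]
    ref = reference_signatures()
    mix = np.asarray(spec.signature_mix, dtype=float)
    expo = np.zeros((spec.n_samples, len(mix)))
    nonzero = mix > 0
    if nonzero.sum() == 1:
        expo[:, nonzero] = 1.0
    else:
        expo[:, nonzero] = mut_rng.dirichlet(
            spec.signature_concentration * mix[nonzero], size=spec.n_samples)
    exposures = pd.DataFrame(expo, index=samples, columns=ref.columns)
    mut_rows = []
    gm_arr = gm.to_numpy()
    for i, s in enumerate(samples):
        n_mut = mut_rng.poisson(spec.mean_mutations)
        n_indel = int(round(spec.indel_fraction * n_mut))
        probs = ref.to_numpy() @ expo[i]
        ctx_counts = mut_rng.multinomial(n_mut - n_indel, probs / probs.sum())
        for ctx_i in np.flatnonzero(ctx_counts):
            label = CONTEXTS_96[ctx_i]
            for _ in range(ctx_counts[ctx_i]):
                mut_rows.append(_snv_row(s, label, gm_arr, mut_rng))
        for _ in range(n_indel):
            g = gm_arr[mut_rng.integers(len(gm_arr))]
            pos = int(mut_rng.integers(g[2], g[3]))
            mut_rows.append(dict(sample=s, gene=g[0], chrom=g[1], pos=pos,
                                 ref="AC", alt="-", variant_class="Frame_Shift_Del",
                                 context="."))
    mutations = pd.DataFrame(
        mut_rows, columns=["sample", "gene", "chrom", "pos", "ref", "alt",
                           "variant_class", "context"])

    # survival: exponential hazards scaled by planted per-label HRs
    surv_rng = rngs["survival"]
    h0 = spec.survival_spec.get("baseline_hazard", 0.02)
    hrs = spec.survival_spec.get("hazard_ratios", {})
    hazard = pd.Series(
        [h0 * hrs.get(clusters[s], 1.0) for s in samples], index=samples, name="hazard"
    )
    t_event = surv_rng.exponential(1.0 / hazard.to_numpy())
    t_cens = surv_rng.uniform(0.0, spec.censor_tmax, size=spec.n_samples)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)
    survival = pd.DataFrame({
        "sample": samples,
        "os_time": np.maximum(os_time, 1e-6),
        "os_event": os_event,
        "cluster": clusters.to_numpy(),
    })

    gene_sets = {f"program_{label}": list(program)
                 for label, _, program, _ in spec.cluster_spec}
    ks_rows = []
    for kinase, sites, _ in spec.kinase_spec:
        for site in sites:
            protein_id, st = site.rsplit("_", 1)
            ks_rows.append(dict(kinase=kinase, substrate=protein_id, site=st,
                                source="synthetic", score=np.nan))
    ks_map = pd.DataFrame(ks_rows, columns=["kinase", "substrate", "site", "source", "score"])

    truth = GroundTruth(
        cluster_labels=clusters,
        arm_carriers=arm_carriers,
        focal_carriers=focal_carriers,
        cis_genes=list(spec.cis_genes),
        kinase_activity=kin_activity,
        signature_exposures=exposures,
        hazards=hazard,
    )
    return Cohort(segments=segments, mutations=mutations, mrna=mrna, protein=protein,
                  phospho=phospho, peptides=peptides, survival=survival, truth=truth,
                  gene_model=gm, gene_sets=gene_sets, ks_map=ks_map,
                  observable_counts=obs_counts)


def _snv_row(sample: str, context_label: str, gm_arr, rng) -> dict:
    """One SNV row from a 96-context label; half are emitted on the
    purine strand to exercise downstream strand collapsing."""
    five, rest = context_label.split("[")
    sub, three = rest.split("]")
    ref, alt = sub.split(">")
    ctx = five + ref + three
    if rng.random() < 0.5:  # purine-strand representation
        ctx = ctx.translate(_COMPLEMENT)[::-1]
        ref = ctx[1]
        alt = alt.translate(_COMPLEMENT)
    g = gm_arr[rng.integers(len(gm_arr))]
    pos = int(rng.integers(g[2], g[3]))
    vc = "Silent" if rng.random() < 0.3 else "Missense_Mutation"
    return dict(sample=sample, gene=g[0], chrom=g[1], pos=pos, ref=ref, alt=alt,
                variant_class=vc, context=ctx)


# ---------------------------------------------------------------------------
# file output


_FILES = {
    "segments": "segments.seg",
    "mutations": "mutations.maf.tsv",
    "mrna": "mrna.gct",
    "protein": "protein.gct",
    "phospho": "phospho.gct",
    "peptides": "peptides.tsv",
    "survival": "survival.tsv",
    "gene_model": "gene_model.tsv",
    "gene_sets": "programs.gmt",
    "ks_map": "kinase_substrates.tsv",
    "clusters": "true_clusters.tsv",
    "observable": "observable_counts.tsv",
}


def write_cohort(outdir: str | os.PathLike, cohort: Cohort, overwrite: bool = False) -> dict:
    """Write every cohort table to ``outdir`` in standard text formats.

    SEG, MAF-like TSV, GCT 1.2 matrices, GMT gene sets and plain TSVs.
    Existing target files raise unless ``overwrite=True``.  Returns the
    mapping of logical names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in _FILES.items()}
    if not overwrite:
        clashes = [str(p) for p in paths.values() if p.exists()]
        if clashes:
            raise FileExistsError(f"refusing to overwrite existing file(s): {clashes}")
    io.write_seg(paths["segments"], cohort.segments)
    io.write_maf(paths["mutations"], cohort.mutations)
    io.write_gct(paths["mrna"], cohort.mrna.data)
    io.write_gct(paths["protein"], cohort.protein.data)
    io.write_gct(paths["phospho"], cohort.phospho.data)
    cohort.peptides.to_csv(paths["peptides"], sep="\t", index=False)
    io.write_survival(paths["survival"], cohort.survival)
    cohort.gene_model.to_csv(paths["gene_model"], sep="\t", index=False)
    io.write_gmt(paths["gene_sets"], cohort.gene_sets)
    cohort.ks_map.to_csv(paths["ks_map"], sep="\t", index=False)
    cohort.truth.cluster_labels.rename("cluster").to_csv(paths["clusters"], sep="\t")
    cohort.observable_counts.rename("observable").to_csv(paths["observable"], sep="\t")
    return {k: str(v) for k, v in paths.items()}
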