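"""Synthetic multi-omics bundles with planted regulatory structure.

The generator emulates the shape of a two-condition tumor cohort: a
genes x samples expression matrix, genome-wide copy-number segments, sparse
binary somatic mutations, and two group labels.  Its purpose is to make
every pipeline stage testable against known ground truth:

* each module of co-expressed genes is driven by one planted modulator
  whose aberration (a CNV segment pushing the gene-level log2 ratio past
  +/-0.3, or a recurrent mutation) sets the module's leaf mean;
* within-group heterogeneity is modelled as a two-component mixture — a
  configurable fraction of each driving group's samples is off-program:
  their module expression stays at the baseline leaf mean regardless of
  the modulator's state (a non-responder subpopulation).  This splits the
  aberrant samples into two modes and produces the multi-modal,
  "no clear clusters" regime that defeats mean-based statistics while
  leaving the regulatory signal recoverable by a nonlinear method;
* passenger genes carry null expression plus background segment CNVs and
  sparse mutations, so the selection funnel has something to reject;
* CNV is emitted as genomic segments (whole chromosomes tiled, aberrations
  as separate segments), so segment-to-gene mapping is exercised for real.

A modulator can drive its module in both groups (shared) or in one group
only; group-specific drivers are what the comparative cross-validation is
meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from drivermod import data_io
from drivermod.data_io import GroupLabels, OmicsBundle

__all__ = ["SimConfig", "ModuleProgram", "SyntheticTruth", "SyntheticDataset", "generate_bundle", "recovery_metrics"]


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults give 5 modules of 20 genes driven by 5 shared modulators over
    60 + 60 samples at effect size 3 noise-sd with 30% off-program mixture
    heterogeneity.  ``n_shared + n_group_a + n_group_b`` modulators must
    equal ``n_modules`` (one driver per module).
    """

    n_samples: tuple[int, int] = (60, 60)
    group_names: tuple[str, str] = ("resistant", "sensitive")
    n_modules: int = 5
    module_size: int = 20
    n_passengers: int = 40
    n_shared_modulators: int = 5
    n_group_a_modulators: int = 0
    n_group_b_modulators: int = 0
    #: leaf-mean separation in units of noise_sd
    effect_size: float = 3.0
    noise_sd: float = 1.0
    #: fraction of each driving group's samples drawn from the off-program component
    mixture_heterogeneity: float = 0.3
    #: aberration rate of a modulator within its driving group(s)
    modulator_cnv_rate: float = 0.85
    modulator_mut_rate: float = 0.30
    background_cnv_rate: float = 0.05
    background_mut_rate: float = 0.01
    cnv_amp_log2: float = 0.8
    background_cnv_log2: float = 0.5
    baseline_log2_sd: float = 0.03
    gene_length: int = 100_000
    gene_spacing: int = 1_000_000
    genes_per_chrom: int = 25
    segment_flank: int = 50_000
    seed: int = 0

    def validate(self) -> None:
        if self.module_size < 1 or self.n_modules < 1:
            raise ValueError("need module_size >= 1 and n_modules >= 1")
        planted = self.n_shared_modulators + self.n_group_a_modulators + self.n_group_b_modulators
        if planted != self.n_modules:
            raise ValueError(
                f"planted modulators ({planted}) must equal n_modules ({self.n_modules}): one driver per module"
            )
        for name in ("mixture_heterogeneity", "modulator_cnv_rate", "modulator_mut_rate", "background_cnv_rate", "background_mut_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if min(self.n_samples) < 4:
            raise ValueError("need >=4 samples per group")
        if self.segment_flank * 2 + self.gene_length >= self.gene_spacing:
            raise ValueError("segment_flank too large for gene_spacing")


@dataclass
class ModuleProgram:
    """Planted regulatory program of one module."""

    module_id: int
    modulator: str
    source: str  # 'cnv' or 'mutation'
    threshold: float
    leaf_mean_high: float  # mean when the modulator is aberrant
    leaf_mean_low: float
    off_mean: float  # mean of the off-program mixture component
    driving_groups: tuple[str, ...]
    cnv_sign: int  # +1 amplification, -1 deletion (cnv source only)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic bundle."""

    shared_modulators: list[str]
    group_specific: dict[str, list[str]]
    gene_module: dict[str, int]
    programs: list[ModuleProgram]

    def modulators_for(self, group: str) -> list[str]:
        return self.shared_modulators + self.group_specific.get(group, [])

    @property
    def all_modulators(self) -> list[str]:
        out = list(self.shared_modulators)
        for gs in self.group_specific.values():
            out.extend(gs)
        return out


@dataclass
class SyntheticDataset:
    bundle: OmicsBundle
    truth: SyntheticTruth
    seg: pd.DataFrame
    coords: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": outdir / "expression.tsv",
            "segments": outdir / "cnv.seg",
            "genes": outdir / "genes.bed",
            "mutations": outdir / "mutations.maf",
            "labels": outdir / "labels.tsv",
        }
        data_io.write_expression(self.bundle.expr, paths["expression"])
        data_io.write_segments(self.seg, paths["segments"])
        data_io.write_gene_coords(self.coords, paths["genes"])
        data_io.write_mutations(self.bundle.mut, paths["mutations"])
        data_io.write_labels(self.bundle.labels, paths["labels"])
        return paths


def expected_mean_shift(cfg: SimConfig, source: str) -> float:
    """Analytic expected group-mean difference for a driven module's genes.

    Driving-group mean = (1-h) * p * effect with p the aberration rate of
    the program's source and h the off-program fraction (off samples sit at
    the baseline mean 0); the non-driving group sits at 0.
    """
    p = cfg.modulator_cnv_rate if source == "cnv" else cfg.modulator_mut_rate
    h = cfg.mixture_heterogeneity
    return (1 - h) * p * cfg.effect_size


def generate_bundle(cfg: SimConfig) -> SyntheticDataset:
    """Generate one synthetic cohort; byte-identical output under one seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ga, gb = cfg.group_names
    n_a, n_b = cfg.n_samples
    samples = [f"{ga[:3].upper()}{i:03d}" for i in range(n_a)] + [f"{gb[:3].upper()}{i:03d}" for i in range(n_b)]
    group_of = np.array([ga] * n_a + [gb] * n_b)
    labels = GroupLabels(pd.Series(group_of, index=samples, name="group"))

    n_mod = cfg.n_modules
    modulator_names = [f"MOD{m:02d}" for m in range(n_mod)]
    module_genes = {m: [f"G{m:02d}_{j:02d}" for j in range(cfg.module_size)] for m in range(n_mod)}
    passenger_names = [f"PSG{j:03d}" for j in range(cfg.n_passengers)]
    genes = modulator_names + [g for m in range(n_mod) for g in module_genes[m]] + passenger_names
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    n_samples = len(samples)

    # genome layout: fixed-size genes on tiled chromosomes
    chrom_of = {}
    start_of = {}
    rows = []
    for i, g in enumerate(genes):
        chrom = str(i // cfg.genes_per_chrom + 1)
        slot = i % cfg.genes_per_chrom
        start = slot * cfg.gene_spacing + 1
        chrom_of[g], start_of[g] = chrom, start
        rows.append((g, chrom, start, start + cfg.gene_length - 1))
    coords = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]).set_index("gene")

    # driving-group schedule: shared first, then A-only, then B-only
    driving: list[tuple[str, ...]] = (
        [(ga, gb)] * cfg.n_shared_modulators + [(ga,)] * cfg.n_group_a_modulators + [(gb,)] * cfg.n_group_b_modulators
    )

    programs: list[ModuleProgram] = []
    aberrant = np.zeros((n_mod, n_samples), dtype=bool)
    for m in range(n_mod):
        source = "cnv" if m % 2 == 0 else "mutation"
        rate = cfg.modulator_cnv_rate if source == "cnv" else cfg.modulator_mut_rate
        drives = driving[m]
        in_driving = np.isin(group_of, drives)
        bg_rate = cfg.background_cnv_rate if source == "cnv" else cfg.background_mut_rate
        p = np.where(in_driving, rate, bg_rate)
        aberrant[m] = rng.random(n_samples) < p
        sign = 1 if (m // 2) % 2 == 0 else -1
        programs.append(
            ModuleProgram(
                module_id=m,
                modulator=modulator_names[m],
                source=source,
                threshold=(cfg.cnv_amp_log2 * sign) / 2 if source == "cnv" else 0.5,
                leaf_mean_high=cfg.effect_size,
                leaf_mean_low=0.0,
                off_mean=0.0,
                driving_groups=drives,
                cnv_sign=sign,
            )
        )

    # ------------------------------------------------------------------ CNV
    # per-(gene, sample) aberration table; modulator programs override background
    bg_aberrant = rng.random((n_genes, n_samples)) < cfg.background_cnv_rate
    bg_sign = np.where(rng.random((n_genes, n_samples)) < 0.5, 1.0, -1.0)
    cnv_value = np.full((n_genes, n_samples), np.nan)
    is_aberrant = np.zeros((n_genes, n_samples), dtype=bool)
    is_aberrant |= bg_aberrant
    aberr_log2 = bg_sign * cfg.background_cnv_log2
    for prog in programs:
        if prog.source != "cnv":
            continue
        gi = gene_pos[prog.modulator]
        # the modulator's CNV is exactly its program state (background rate
        # outside the driving groups is already folded into `aberrant`)
        is_aberrant[gi, :] = aberrant[prog.module_id]
        aberr_log2[gi, :] = prog.cnv_sign * cfg.cnv_amp_log2
    # one baseline log2 per (sample, chromosome)
    chroms = sorted({chrom_of[g] for g in genes}, key=int)
    baseline = {
        (s, c): float(rng.normal(0.0, cfg.baseline_log2_sd)) for c in chroms for s in samples
    }

    seg_rows = []
    genes_by_chrom: dict[str, list[str]] = {}
    for g in genes:
        genes_by_chrom.setdefault(chrom_of[g], []).append(g)
    chrom_len = cfg.genes_per_chrom * cfg.gene_spacing
    for si, s in enumerate(samples):
        for c in chroms:
            b = baseline[(s, c)]
            cursor = 1
            for g in genes_by_chrom[c]:
                gi = gene_pos[g]
                gs, ge = start_of[g], start_of[g] + cfg.gene_length - 1
                if is_aberrant[gi, si]:
                    seg_start = max(cursor, gs - cfg.segment_flank)
                    seg_end = ge + cfg.segment_flank
                    if seg_start > cursor:
                        seg_rows.append((s, c, cursor, seg_start - 1, b))
                    seg_rows.append((s, c, seg_start, seg_end, float(aberr_log2[gi, si])))
                    cursor = seg_end + 1
                    cnv_value[gi, si] = aberr_log2[gi, si]
                else:
                    cnv_value[gi, si] = b
            if cursor <= chrom_len:
                seg_rows.append((s, c, cursor, chrom_len, b))
    seg = pd.DataFrame(seg_rows, columns=data_io.SEG_COLUMNS)

    # ------------------------------------------------------------- mutations
    mut = (rng.random((n_genes, n_samples)) < cfg.background_mut_rate).astype(np.int8)
    for prog in programs:
        if prog.source != "mutation":
            continue
        mut[gene_pos[prog.modulator], :] = aberrant[prog.module_id].astype(np.int8)

    # ------------------------------------------------------------ expression
    expr = rng.normal(0.0, cfg.noise_sd, size=(n_genes, n_samples))
    gene_module: dict[str, int] = {}
    for prog in programs:
        m = prog.module_id
        in_driving = np.isin(group_of, prog.driving_groups)
        # off-program (non-responder) samples ignore the modulator state
        off = (rng.random(n_samples) < cfg.mixture_heterogeneity) & in_driving
        on_high = in_driving & ~off & aberrant[m]
        mean = np.full(n_samples, prog.off_mean)
        mean[on_high] = prog.leaf_mean_high
        for g in module_genes[m]:
            gene_module[g] = m
            expr[gene_pos[g]] += mean
        # cis effect on the modulator's own expression
        expr[gene_pos[prog.modulator]] += np.where(aberrant[m], 0.5 * cfg.effect_size * (prog.cnv_sign if prog.source == "cnv" else 1), 0.0)

    expr_df = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples)
    cnv_df = pd.DataFrame(cnv_value, index=pd.Index(genes, name="gene"), columns=samples)
    mut_df = pd.DataFrame(mut, index=pd.Index(genes, name="gene"), columns=samples)
    bundle = OmicsBundle(expr=expr_df, cnv=cnv_df, mut=mut_df, labels=labels)

    truth = SyntheticTruth(
        shared_modulators=modulator_names[: cfg.n_shared_modulators],
        group_specific={
            ga: modulator_names[cfg.n_shared_modulators : cfg.n_shared_modulators + cfg.n_group_a_modulators],
            gb: modulator_names[cfg.n_shared_modulators + cfg.n_group_a_modulators :],
        },
        gene_module=gene_module,
        programs=programs,
    )
    return SyntheticDataset(bundle=bundle, truth=truth, seg=seg, coords=coords)


def recovery_metrics(truth: SyntheticTruth, recovered, group: str | None = None) -> dict:
    """Precision/recall of planted modulators in a result object.

    ``recovered`` may be a ModulatorRanking, a CrossValReport (its
    signature), or any iterable of gene names.  ``group`` restricts the
    planted reference to the modulators active in that group; default is
    all planted modulators.  Empty results report precision 0 with a flag.
    """
    if hasattr(recovered, "modulators"):
        found = list(recovered.modulators)
    elif hasattr(recovered, "signature"):
        found = list(recovered.signature)
    else:
        found = list(recovered)
    planted = truth.modulators_for(group) if group is not None else truth.all_modulators
    planted_set, found_set = set(planted), set(found)
    tp = len(planted_set & found_set)
    recall = tp / len(planted_set) if planted_set else 0.0
    empty = len(found_set) == 0
    precision = 0.0 if empty else tp / len(found_set)
    return {
        "recall": recall,
        "precision": precision,
        "n_planted": len(planted_set),
        "n_recovered": len(found_set),
        "n_true_positive": tp,
        "empty_result": empty,
    }


def module_agreement(truth: SyntheticTruth, assignment: dict[str, int]) -> dict:
    """Agreement between planted and learned module structure.

    Reports the adjusted Rand index over genes present in both maps and the
    best-match overlap (each true module matched to the learned module
    sharing most genes; fraction of genes so matched).
    """
    from sklearn.metrics import adjusted_rand_score

    common = [g for g in truth.gene_module if g in assignment]
    if not common:
        return {"ari": 0.0, "best_match_overlap": 0.0, "n_genes": 0}
    t = [truth.gene_module[g] for g in common]
    l = [assignment[g] for g in common]
    ari = adjusted_rand_score(t, l)
    overlap = 0
    for tm in set(t):
        members = [g for g in common if truth.gene_module[g] == tm]
        counts: dict[int, int] = {}
        for g in members:
            counts[assignment[g]] = counts.get(assignment[g], 0) + 1
        overlap += max(counts.values())
    return {"ari": float(ari), "best_match_overlap": overlap / len(common), "n_genes": len(common)}
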