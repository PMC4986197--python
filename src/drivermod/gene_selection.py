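"""The differential selection funnel and candidate-modulator rules.

Four criteria admit a gene into the integrative analysis; the final list is
their union:

* expression EMD q-value < 0.1;
* gene-level CNV EMD q-value < 0.1 (EMD on the continuous log2 matrix);
* amplification- or deletion-frequency difference between groups > 20%
  (calls at log2 ratio > 0.3 / < -0.3);
* somatic mutation frequency > 2% within a group.

All thresholds are strict ("more than"): a value exactly at a threshold
fails.  Candidate modulators for a condition are genes aberrant at high
within-group frequency: mutation frequency > 2% OR amplified-or-deleted
CNV frequency > 70%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from drivermod.emd_stats import EMDConfig, EMDResult, compute_emd_table, permutation_qvalues

if TYPE_CHECKING:
    from drivermod.data_io import GroupLabels, OmicsBundle

logger = logging.getLogger(__name__)

AMPLIFIED, NEUTRAL, DELETED = 1, 0, -1


@dataclass
class SelectionConfig:
    """Thresholds of the selection funnel and modulator rules."""

    amp_thresh: float = 0.3
    del_thresh: float = -0.3
    min_freq_diff: float = 0.20
    min_mut_freq: float = 0.02
    modulator_mut_min: float = 0.02
    modulator_cnv_min: float = 0.70
    #: per-group mutation frequencies (pooled across groups if False)
    mutation_per_group: bool = True
    #: 'or' admits a candidate modulator on either criterion; 'and' on both
    modulator_combiner: str = "or"
    emd: EMDConfig = field(default_factory=EMDConfig)

    def validate(self) -> None:
        if not self.del_thresh < 0 < self.amp_thresh:
            raise ValueError("need del_thresh < 0 < amp_thresh")
        for name in ("min_freq_diff", "min_mut_freq", "modulator_mut_min", "modulator_cnv_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.modulator_combiner not in ("or", "and"):
            raise ValueError("modulator_combiner must be 'or' or 'and'")
        self.emd.validate()


@dataclass
class SelectionResult:
    """Per-criterion flags, the union gene list, and per-group modulators."""

    flags: pd.DataFrame  # boolean columns: expr_emd, cnv_emd, cnv_freq, mut_freq
    selected_genes: list[str]
    candidate_modulators: dict[str, list[str]]
    emd_expr: EMDResult
    emd_cnv: EMDResult
    freq_table: pd.DataFrame

    def write_tsv(self, path) -> None:
        out = self.flags.copy()
        out["selected"] = out.any(axis=1)
        out.join(self.freq_table, how="left").to_csv(path, sep="\t", float_format="%.6g", index_label="gene")


def map_segments_to_genes(seg: pd.DataFrame, coords: pd.DataFrame, samples: Sequence[str]) -> pd.DataFrame:
    """Gene-level log2 copy ratios by overlap-weighted averaging of segments.

    For each (gene, sample), the value is the mean of the log2 ratios of the
    segments overlapping the gene, weighted by overlap length in bp; NaN if
    no segment overlaps.  Coordinates are 1-based inclusive on both sides.
    """
    genes = list(coords.index)
    out = np.full((len(genes), len(samples)), np.nan)
    gene_pos = {g: i for i, g in enumerate(genes)}
    coords_by_chrom: dict[str, pd.DataFrame] = {str(c): d for c, d in coords.groupby("chrom")}
    seg_chroms = set(seg["chrom"].unique())
    missing_chroms = set(coords_by_chrom) - seg_chroms
    if missing_chroms:
        n = sum(len(coords_by_chrom[c]) for c in missing_chroms)
        logger.info("%d genes on %d chromosomes absent from SEG; left missing", n, len(missing_chroms))
    for (sample, chrom), segs in seg.groupby(["sample", "chrom"], sort=False):
        if sample not in set(samples) or str(chrom) not in coords_by_chrom:
            continue
        j = list(samples).index(sample)
        segs = segs.sort_values("start")
        starts = segs["start"].to_numpy()
        ends = segs["end"].to_numpy()
        log2 = segs["log2"].to_numpy(dtype=float)
        gsub = coords_by_chrom[str(chrom)]
        for gene, row in gsub.iterrows():
            gs, ge = int(row["start"]), int(row["end"])
            # segments are sorted and non-overlapping: candidates have
            # start <= ge and end >= gs
            lo = int(np.searchsorted(ends, gs, side="left"))
            hi = int(np.searchsorted(starts, ge, side="right"))
            if hi <= lo:
                continue
            ov = np.minimum(ends[lo:hi], ge) - np.maximum(starts[lo:hi], gs) + 1
            keep = ov > 0
            if not keep.any():
                continue
            vals = log2[lo:hi][keep]
            if vals.size == 1:  # fully inside one segment: exact, no rounding
                out[gene_pos[gene], j] = float(vals[0])
            else:
                w = ov[keep].astype(float)
                out[gene_pos[gene], j] = float(np.dot(w, vals) / w.sum())
    return pd.DataFrame(out, index=pd.Index(genes, name="gene"), columns=list(samples))


def call_cnv_states(cnv_matrix: pd.DataFrame, amp_thresh: float = 0.3, del_thresh: float = -0.3) -> pd.DataFrame:
    """Ternary amplification/deletion calls from gene-level log2 ratios.

    Amplified iff log2 > ``amp_thresh``; deleted iff log2 < ``del_thresh``
    (both strict); otherwise neutral.  Missing stays missing (NaN).
    """
    if not del_thresh < 0 < amp_thresh:
        raise ValueError("need del_thresh < 0 < amp_thresh")
    vals = cnv_matrix.to_numpy(dtype=float)
    calls = np.where(vals > amp_thresh, float(AMPLIFIED), np.where(vals < del_thresh, float(DELETED), float(NEUTRAL)))
    calls = np.where(np.isfinite(vals), calls, np.nan)
    return pd.DataFrame(calls, index=cnv_matrix.index, columns=cnv_matrix.columns)


def _group_masks(labels: "GroupLabels", columns: Sequence[str]) -> dict[str, np.ndarray]:
    return {g: np.array([labels.series.get(s) == g for s in columns]) for g in labels.groups}


def _call_freqs(calls: pd.DataFrame, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(amp, del) frequencies over non-missing samples of the mask; NaN if none."""
    sub = calls.to_numpy(dtype=float)[:, mask]
    n = np.isfinite(sub).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = np.where(n > 0, np.nansum(sub == AMPLIFIED, axis=1) / n, np.nan)
        dele = np.where(n > 0, np.nansum(sub == DELETED, axis=1) / n, np.nan)
    return amp, dele


def cnv_frequency_filter(calls: pd.DataFrame, labels: "GroupLabels", min_diff: float = 0.20) -> pd.Series:
    """Flag genes whose amp or del frequency differs between groups by more than ``min_diff``."""
    ga, gb = labels.groups
    masks = _group_masks(labels, list(calls.columns))
    amp_a, del_a = _call_freqs(calls, masks[ga])
    amp_b, del_b = _call_freqs(calls, masks[gb])
    with np.errstate(invalid="ignore"):
        flag = (np.abs(amp_a - amp_b) > min_diff) | (np.abs(del_a - del_b) > min_diff)
    flag = np.where(np.isnan(amp_a) | np.isnan(amp_b), False, flag)
    return pd.Series(flag.astype(bool), index=calls.index, name="cnv_freq")


def mutation_frequency_filter(
    mut: pd.DataFrame, labels: "GroupLabels", min_freq: float = 0.02, per_group: bool = True
) -> pd.Series:
    """Flag genes mutated in more than ``min_freq`` of a group's tumors."""
    cols = list(mut.columns)
    vals = mut.to_numpy(dtype=float)
    if per_group:
        flag = np.zeros(len(mut.index), dtype=bool)
        for g, mask in _group_masks(labels, cols).items():
            if mask.sum() == 0:
                continue
            flag |= vals[:, mask].mean(axis=1) > min_freq
    else:
        labeled = np.array([s in set(labels.samples) for s in cols])
        flag = vals[:, labeled].mean(axis=1) > min_freq
    return pd.Series(flag, index=mut.index, name="mut_freq")


def select_candidate_modulators(
    calls: pd.DataFrame,
    mut: pd.DataFrame,
    labels: "GroupLabels | None",
    group: str | None,
    mut_min: float = 0.02,
    cnv_min: float = 0.70,
    combiner: str = "or",
) -> list[str]:
    """Genes aberrant at high frequency within ``group``.

    Mutation frequency > ``mut_min`` or amplified-or-deleted fraction >
    ``cnv_min`` (strict; ``combiner='and'`` requires both).  ``group=None``
    computes frequencies over all samples.  Sorted by descending max
    frequency, ties alphabetical.
    """
    if group is not None:
        if labels is None:
            raise ValueError("labels required when group is given")
        samples = labels.group_samples(group)
    else:
        samples = list(calls.columns)
    scores: dict[str, float] = {}
    chosen: list[str] = []
    cnv_cols = [s for s in samples if s in set(calls.columns)]
    mut_cols = [s for s in samples if s in set(mut.columns)]
    cnv_sub = calls[cnv_cols].to_numpy(dtype=float) if cnv_cols else None
    mut_sub = mut[mut_cols].to_numpy(dtype=float) if mut_cols else None

    cnv_freq: dict[str, float] = {}
    if cnv_sub is not None:
        n = np.isfinite(cnv_sub).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n > 0, np.nansum(cnv_sub != NEUTRAL, axis=1) / n, 0.0)
        cnv_freq = dict(zip(calls.index, freq))
    mut_freq: dict[str, float] = {}
    if mut_sub is not None and mut_sub.shape[1] > 0:
        mut_freq = dict(zip(mut.index, mut_sub.mean(axis=1)))

    for gene in sorted(set(cnv_freq) | set(mut_freq)):
        cf = cnv_freq.get(gene, 0.0)
        mf = mut_freq.get(gene, 0.0)
        hit_cnv = cf > cnv_min
        hit_mut = mf > mut_min
        hit = (hit_cnv and hit_mut) if combiner == "and" else (hit_cnv or hit_mut)
        if hit:
            chosen.append(gene)
            scores[gene] = max(cf, mf)
    chosen.sort(key=lambda g: (-scores[g], g))
    return chosen


def build_selection(
    emd_expr: EMDResult,
    emd_cnv: EMDResult,
    cnv_flag: pd.Series,
    mut_flag: pd.Series,
    cfg: SelectionConfig,
    candidate_modulators: dict[str, list[str]] | None = None,
) -> SelectionResult:
    """Union of the four selection criteria over the joint gene universe."""
    qt = cfg.emd.q_threshold
    expr_sel = set(emd_expr.selected(qt))
    cnv_sel = set(emd_cnv.selected(qt))
    universe = sorted(
        set(emd_expr.table.index) | set(emd_cnv.table.index) | set(cnv_flag.index) | set(mut_flag.index)
    )
    flags = pd.DataFrame(
        {
            "expr_emd": [g in expr_sel for g in universe],
            "cnv_emd": [g in cnv_sel for g in universe],
            "cnv_freq": [bool(cnv_flag.get(g, False)) for g in universe],
            "mut_freq": [bool(mut_flag.get(g, False)) for g in universe],
        },
        index=pd.Index(universe, name="gene"),
    )
    selected = list(flags.index[flags.any(axis=1)])
    if not selected:
        raise ValueError(
            "no gene passed any selection criterion; relax q_threshold or the frequency thresholds"
        )
    freq = pd.DataFrame(index=flags.index)
    return SelectionResult(
        flags=flags,
        selected_genes=selected,
        candidate_modulators=candidate_modulators or {},
        emd_expr=emd_expr,
        emd_cnv=emd_cnv,
        freq_table=freq,
    )


def select_genes(bundle: "OmicsBundle", cfg: SelectionConfig | None = None) -> SelectionResult:
    """Run the full selection funnel on an aligned bundle.

    EMD scoring runs on expression and on the continuous gene-level CNV
    matrix (independent permutation nulls, seeds offset to decorrelate);
    the frequency filters run on the ternary calls and the binary mutation
    matrix.  Per-group candidate-modulator lists are attached.
    """
    cfg = cfg or SelectionConfig()
    cfg.validate()
    labels = bundle.labels

    obs_expr = compute_emd_table(bundle.expr, labels, cfg.emd)
    emd_expr = permutation_qvalues(obs_expr, bundle.expr, labels, cfg.emd)

    cnv_cfg = EMDConfig(
        n_bins=cfg.emd.n_bins,
        n_permutations=cfg.emd.n_permutations,
        seed=cfg.emd.seed + 1,
        q_threshold=cfg.emd.q_threshold,
        max_missing_frac=cfg.emd.max_missing_frac,
    )
    obs_cnv = compute_emd_table(bundle.cnv, labels, cnv_cfg)
    emd_cnv = permutation_qvalues(obs_cnv, bundle.cnv, labels, cnv_cfg)

    calls = call_cnv_states(bundle.cnv, cfg.amp_thresh, cfg.del_thresh)
    cnv_flag = cnv_frequency_filter(calls, labels, cfg.min_freq_diff)
    mut_flag = mutation_frequency_filter(bundle.mut, labels, cfg.min_mut_freq, cfg.mutation_per_group)

    candidates = {
        g: select_candidate_modulators(
            calls,
            bundle.mut,
            labels,
            g,
            mut_min=cfg.modulator_mut_min,
            cnv_min=cfg.modulator_cnv_min,
            combiner=cfg.modulator_combiner,
        )
        for g in labels.groups
    }
    result = build_selection(emd_expr, emd_cnv, cnv_flag, mut_flag, cfg, candidates)

    # per-group frequency annotations for the output table
    freq = {}
    for g in labels.groups:
        mask = np.array([labels.series.get(s) == g for s in calls.columns])
        amp, dele = _call_freqs(calls, mask)
        freq[f"amp_freq_{g}"] = pd.Series(amp, index=calls.index)
        freq[f"del_freq_{g}"] = pd.Series(dele, index=calls.index)
        mmask = np.array([labels.series.get(s) == g for s in bundle.mut.columns])
        if mmask.any():
            freq[f"mut_freq_{g}"] = pd.Series(bundle.mut.to_numpy(dtype=float)[:, mmask].mean(axis=1), index=bundle.mut.index)
    result.freq_table = pd.DataFrame(freq).reindex(result.flags.index)
    return result
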