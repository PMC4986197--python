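"""Per-condition comparative analysis and paired leave-one-out cross-validation.

The module network is trained once per condition on that condition's
samples.  The module-member gene list is shared (computed once from the
two-group selection funnel on the full cohort), but candidate modulators
are condition-specific: genes aberrant at high frequency *within* that
condition.  Driver candidates for condition A are modulators of A's
network absent from B's.

Cross-validation removes one sample from each group per iteration (a
seeded random pairing), reruns the entire funnel — selection, per-condition
modulators, both networks — on the reduced cohort, and counts how often
each gene appears as a modulator per condition.  The final signature is
the set of genes with modulator frequency above the inclusion threshold
(default 0.8, strict) in the first condition and at most the exclusion
threshold (default 0.2) in the second.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from drivermod.data_io import OmicsBundle, GroupLabels
from drivermod.gene_selection import SelectionConfig, call_cnv_states, select_candidate_modulators, select_genes
from drivermod.module_network import ModuleNetworkConfig, ModulatorRanking, learn_network

logger = logging.getLogger(__name__)

__all__ = ["CrossValConfig", "CrossValReport", "run_condition", "compare_modulators", "loo_crossval"]


@dataclass
class CrossValConfig:
    """Settings for the comparative run and the LOO loop."""

    #: inclusion rule: modulator frequency in the first group must exceed this
    freq_threshold: float = 0.8
    #: exclusion rule: frequency in the second group must not exceed this
    exclusion_threshold: float = 0.2
    #: number of paired-removal iterations; None = min(group sizes)
    n_iterations: int | None = None
    #: iterate over the full n_a x n_b grid of removal pairs
    all_pairs: bool = False
    #: tolerated fraction of failed iterations before aborting
    max_failure_frac: float = 0.2
    seed: int = 0
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    network: ModuleNetworkConfig = field(default_factory=ModuleNetworkConfig)

    def validate(self) -> None:
        if not 0 < self.freq_threshold <= 1:
            raise ValueError("freq_threshold must be in (0,1]")
        if not 0 <= self.exclusion_threshold <= 1:
            raise ValueError("exclusion_threshold must be in [0,1]")
        self.selection.validate()


@dataclass
class CrossValReport:
    """Per-gene modulator frequencies across LOO iterations and the signature."""

    frequencies: pd.DataFrame  # columns freq_<groupA>, freq_<groupB>, in_signature
    signature: list[str]
    iterations: list[dict]
    n_failed: int
    groups: tuple[str, str]

    def write_tsv(self, path) -> None:
        self.frequencies.to_csv(path, sep="\t", float_format="%.6g", index_label="gene")

    def write_iterations_jsonl(self, path) -> None:
        import json

        with open(path, "w") as fh:
            for it in self.iterations:
                fh.write(json.dumps(it, default=str) + "\n")


def run_condition(
    bundle: OmicsBundle,
    condition: str,
    shared_selected_genes: list[str],
    cfg: CrossValConfig | None = None,
) -> ModulatorRanking:
    """Train the module network on one condition's samples only.

    Candidate modulators are recomputed within the condition; the module
    member list is the shared selection from the full two-group funnel.
    """
    cfg = cfg or CrossValConfig()
    samples = bundle.group_samples(condition)
    if len(samples) < 2 * cfg.network.min_leaf:
        raise ValueError(
            f"group {condition!r} has {len(samples)} samples; need >= {2 * cfg.network.min_leaf}"
        )
    sel = cfg.selection
    calls = call_cnv_states(bundle.cnv, sel.amp_thresh, sel.del_thresh)
    candidates = select_candidate_modulators(
        calls,
        bundle.mut,
        bundle.labels,
        condition,
        mut_min=sel.modulator_mut_min,
        cnv_min=sel.modulator_cnv_min,
        combiner=sel.modulator_combiner,
    )
    sub = _single_group_bundle(bundle, condition)
    _, ranking = learn_network(sub, shared_selected_genes, candidates, cfg.network)
    return ranking


def _single_group_bundle(bundle: OmicsBundle, condition: str) -> OmicsBundle:
    """Restrict to one group's samples.

    GroupLabels enforces two groups, which a single-condition training set
    cannot satisfy, so the restricted bundle is built without re-running
    validation; the network learner never consults the labels.
    """
    samples = bundle.group_samples(condition)
    series = pd.Series([condition] * len(samples), index=samples, name="group")
    labels = object.__new__(GroupLabels)
    object.__setattr__(labels, "series", series)
    sub = OmicsBundle.__new__(OmicsBundle)
    sub.expr = bundle.expr[samples]
    sub.cnv = bundle.cnv[samples]
    sub.mut = bundle.mut[samples]
    sub.labels = labels
    return sub


def compare_modulators(rank_a: ModulatorRanking, rank_b: ModulatorRanking) -> list[str]:
    """Modulators of A absent from B, preserving A's ranking order."""
    in_b = set(rank_b.modulators)
    return [g for g in rank_a.modulators if g not in in_b]


def loo_crossval(bundle: OmicsBundle, cfg: CrossValConfig | None = None) -> CrossValReport:
    """Paired leave-one-out cross-validation of the full comparative funnel."""
    cfg = cfg or CrossValConfig()
    cfg.validate()
    ga, gb = bundle.groups
    samples_a = bundle.group_samples(ga)
    samples_b = bundle.group_samples(gb)
    if len(samples_a) < 4 or len(samples_b) < 4:
        raise ValueError("both groups need >= 4 samples for LOO")
    rng = np.random.default_rng(cfg.seed)
    if cfg.all_pairs:
        pairs = [(a, b) for a in samples_a for b in samples_b]
    else:
        perm_a = [samples_a[i] for i in rng.permutation(len(samples_a))]
        perm_b = [samples_b[i] for i in rng.permutation(len(samples_b))]
        n_iter = min(len(samples_a), len(samples_b))
        if cfg.n_iterations is not None:
            n_iter = min(n_iter, cfg.n_iterations)
        pairs = list(zip(perm_a[:n_iter], perm_b[:n_iter]))

    iterations: list[dict] = []
    counts: dict[str, dict[str, int]] = {ga: {}, gb: {}}
    n_failed = 0
    for i, (sa, sb) in enumerate(pairs):
        record = {"iteration": i, "removed": [sa, sb], "failed": False, "modulators": {}}
        try:
            reduced = bundle.drop_samples([sa, sb])
            sel = select_genes(reduced, cfg.selection)
            record["n_selected"] = len(sel.selected_genes)
            for g in (ga, gb):
                ranking = run_condition(reduced, g, sel.selected_genes, cfg)
                record["modulators"][g] = list(ranking.modulators)
        except (ValueError, AssertionError) as exc:
            logger.warning("LOO iteration %d failed: %s", i, exc)
            record["failed"] = True
            record["error"] = str(exc)
            n_failed += 1
            iterations.append(record)
            continue
        for g in (ga, gb):
            for gene in record["modulators"][g]:
                counts[g][gene] = counts[g].get(gene, 0) + 1
        iterations.append(record)

    n_done = len(pairs) - n_failed
    if len(pairs) and n_failed / len(pairs) > cfg.max_failure_frac:
        raise RuntimeError(f"{n_failed}/{len(pairs)} LOO iterations failed")
    genes = sorted(set(counts[ga]) | set(counts[gb]))
    freq_a = np.array([counts[ga].get(g, 0) / n_done if n_done else 0.0 for g in genes])
    freq_b = np.array([counts[gb].get(g, 0) / n_done if n_done else 0.0 for g in genes])
    in_sig = (freq_a > cfg.freq_threshold) & (freq_b <= cfg.exclusion_threshold)
    frequencies = pd.DataFrame(
        {f"freq_{ga}": freq_a, f"freq_{gb}": freq_b, "in_signature": in_sig},
        index=pd.Index(genes, name="gene"),
    )
    signature = [g for g, keep in zip(genes, in_sig) if keep]
    return CrossValReport(
        frequencies=frequencies, signature=signature, iterations=iterations, n_failed=n_failed, groups=(ga, gb)
    )
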