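"""End-to-end workflows over the synthetic selection simulator.

These compose the pipeline stages — simulate, filter/collapse/translate,
enrichment, register assignment, predictor training — into reproducible
experiments with known planted ground truth, and report recovery metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata

from .designs import AA_INDEX, AA_ORDER, LibraryDesign, builtin_design
from .enrichment import log2_enrichment, positional_frequencies, uniprot_background
from .predictor import TrainConfig, make_training_set, predict_many, train_ensemble
from .reads import filter_reads, process_rounds
from .registers import assign_registers, build_pssm
from .simulate import (GroundTruthModel, annotate_truth, default_ground_truth,
                       inject_errors, sample_naive, simulate_selection)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent sub-seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


@dataclass
class SyntheticRun:
    design: LibraryDesign
    model: GroundTruthModel
    table: pd.DataFrame
    attrition: dict
    enrichment: object
    registers: pd.DataFrame | None
    metrics: dict


def run_synthetic_benchmark(seed: int, design_name: str = "dr401_9mer",
                            n_naive: int = 100_000, n_rounds: int = 5,
                            carryover: int = 100_000, sub_rate: float = 1e-3,
                            low_q_fraction: float = 0.02) -> SyntheticRun:
    """Simulate a full selection, run the pipeline, and score recovery.

    Metrics reported:

    * ``motif_pearson_r``: Pearson correlation between the final-round
      log2-enrichment matrix and the planted PSSM.
    * ``register_recovery``: fraction of truth-map binders in the final-round
      table assigned the designed register by the enrichment-derived PSSM.
    * ``parent_recovery`` / ``error_child_removal``: Hamming-collapse
      performance against the truth map in the final round.
    """
    s = _child_seeds(seed, 8)
    design = builtin_design(design_name)
    model = default_ground_truth(design)

    naive = sample_naive(design, n_naive, s[0])
    annotate_truth(naive, design, model, s[1])
    rounds = simulate_selection(naive, model, n_rounds, carryover, s[2], design=design)
    clean_sets = [naive] + rounds
    noisy_sets = [inject_errors(rs, sub_rate, low_q_fraction, s[3] + i)
                  for i, rs in enumerate(clean_sets)]

    table, attrition = process_rounds(noisy_sets, design)

    rs_slice = design.randomized_slice
    r_final = n_rounds
    naive_peps = table.loc[table[f"reads_r0"] > 0, "peptide"]
    final_peps = table.loc[table[f"reads_r{r_final}"] > 0, "peptide"]
    naive_freq = positional_frequencies(naive_peps, rs_slice.start, design.n_random)
    final_freq = positional_frequencies(final_peps, rs_slice.start, design.n_random)
    enrich = log2_enrichment(final_freq, naive_freq, round=r_final)

    metrics: dict = {"n_unique_final": len(final_peps), "n_unique_naive": len(naive_peps)}

    registers = None
    if design.n_random == 9:
        pssm = build_pssm(enrich)
        r_flat = pearsonr(enrich.log2fc.to_numpy().ravel(), model.pssm.ravel())
        metrics["motif_pearson_r"] = float(r_flat.statistic)

        clean_final = clean_sets[-1]
        binder_peps = sorted({pep for pep, off, b in clean_final.truth.values() if b})
        observed = set(final_peps)
        binders_observed = [p for p in binder_peps if p in observed]
        registers = assign_registers(binders_observed, pssm, design.expected_core_offset)
        metrics["register_recovery"] = float(registers["in_register"].mean())
        metrics["n_binders_scored"] = len(binders_observed)

        metrics.update(_collapse_metrics(noisy_sets[-1], clean_sets[-1], design))
        metrics["enrichment"] = enrich
        metrics["pssm"] = pssm
    else:
        r13 = pearsonr(enrich.log2fc.to_numpy()[2:11].ravel(), model.pssm.ravel())
        metrics["motif_pearson_r_central"] = float(r13.statistic)
        metrics["enrichment"] = enrich

    return SyntheticRun(design=design, model=model, table=table,
                        attrition=attrition, enrichment=enrich,
                        registers=registers, metrics=metrics)


def _collapse_metrics(noisy_final, clean_final, design: LibraryDesign) -> dict:
    """Parent recovery / error-child removal of the filter+collapse stages.

    ``error_child_removal`` counts all corrupted sequences that passed the
    filters; ``error_child_removal_removable`` restricts to children whose
    error-free parent was observed at strictly higher prevalence in the same
    round — the only children a more-prevalent-neighbor collapse rule can
    remove even in principle (children orphaned from, or tied with, their
    parent are indistinguishable from genuine singletons).
    """
    from .reads import collapse_errors

    bl = design.barcode_length
    pep_start = bl + len(design.constant5_dna)
    pep_end = pep_start + 3 * design.peptide_length
    parents = {d[pep_start:pep_end] for d, _ in clean_final.records}
    parent_region_of = {c[pep_start:pep_end]: p[pep_start:pep_end]
                        for c, p in noisy_final.parent_of.items()}

    tables, _ = filter_reads(noisy_final, design)
    if clean_final.round not in tables:
        return {}
    raw = tables[clean_final.round]
    collapsed = collapse_errors(raw)
    raw_parents = {d for d in raw.counts if d in parents}
    raw_children = {d for d in raw.counts if d not in parents}
    removable = {d for d in raw_children
                 if raw.counts.get(parent_region_of.get(d, ""), 0) > raw.counts[d]}
    kept = set(collapsed.counts)
    out = {}
    if raw_parents:
        out["parent_recovery"] = len(raw_parents & kept) / len(raw_parents)
    if raw_children:
        out["error_child_removal"] = 1 - len(raw_children & kept) / len(raw_children)
    if removable:
        out["error_child_removal_removable"] = 1 - len(removable & kept) / len(removable)
    out["n_raw_parents"] = len(raw_parents)
    out["n_raw_children"] = len(raw_children)
    return out


def rank_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Mann-Whitney AUC (ties counted half)."""
    s = np.concatenate([scores_pos, scores_neg])
    ranks = rankdata(s)
    n_pos, n_neg = len(scores_pos), len(scores_neg)
    return float((ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def train_and_evaluate(table: pd.DataFrame, design: LibraryDesign, seed: int,
                       cap: int = 12_000, holdout_frac: float = 0.2,
                       config: TrainConfig | None = None):
    """Train a round-weighted ensemble and report held-out AUC vs naive-only.

    A seeded ``holdout_frac`` of the peptide table is set aside before
    training; the AUC contrasts held-out final-round-enriched peptides
    against held-out naive-only peptides (the same positive/decoy definition
    used when benchmarking against a selection repertoire).
    """
    if config is None:
        config = TrainConfig.small()
    s = _child_seeds(seed, 4)
    rng = np.random.default_rng(s[0])
    perm = rng.permutation(len(table))
    n_hold = int(round(holdout_frac * len(table)))
    hold = table.iloc[perm[:n_hold]]
    train = table.iloc[perm[n_hold:]]

    examples = make_training_set(train, design, cap=cap, seed=s[1])
    ensemble = train_ensemble(examples, config, seed=s[2])

    rs = design.randomized_slice
    r_max = max(int(c.split("_r")[1]) for c in table.columns if c.startswith("reads_r"))
    hold_pos = [p[rs] for p, fr in zip(hold["peptide"], hold["final_round"]) if fr == r_max]
    hold_neg = [p[rs] for p, fr in zip(hold["peptide"], hold["final_round"]) if fr == 0]
    auc = None
    if hold_pos and hold_neg:
        sp = predict_many(ensemble, hold_pos)["score"].to_numpy()
        sn = predict_many(ensemble, hold_neg)["score"].to_numpy()
        auc = rank_auc(sp, sn)
    return ensemble, {"holdout_auc": auc, "n_holdout_pos": len(hold_pos),
                      "n_holdout_neg": len(hold_neg), "n_train_examples": len(examples)}


def planted_motif_peptides(n: int, length: int, anchors: dict[int, str],
                           seed: int, anchor_p: float = 0.9,
                           background: pd.Series | None = None) -> list[str]:
    """Unique peptides carrying a planted anchor motif.

    At each anchor position, with probability ``anchor_p`` a residue is drawn
    uniformly from the anchor set, otherwise (and at all other positions)
    from the background frequencies.
    """
    if background is None:
        background = uniprot_background()
    rng = np.random.default_rng(seed)
    p_bg = background.reindex(list(AA_ORDER)).to_numpy()
    p_bg = p_bg / p_bg.sum()
    out: list[str] = []
    seen = set()
    while len(out) < n:
        m = n - len(out)
        draw = rng.choice(20, size=(m, length), p=p_bg)
        for pos, residues in anchors.items():
            mask = rng.random(m) < anchor_p
            choices = np.array([AA_INDEX[a] for a in residues])
            draw[mask, pos] = choices[rng.integers(0, len(choices), size=int(mask.sum()))]
        aas = np.frombuffer(AA_ORDER.encode(), dtype=np.uint8)
        for row in aas[draw].view(f"S{length}").ravel():
            s = row.decode()
            if s not in seen:
                seen.add(s)
                out.append(s)
                if len(out) == n:
                    break
    return out
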