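"""Amplicon read processing: filter cascade, Hamming error collapse, translation.

Converts merged amplicon reads into a clean per-round table of unique
peptides. A read survives the filter cascade iff it has (a) the exact expected
length, (b) exact matches to both constant regions (which carry the
3C-protease-site coding sequence and the allele-identifying polymorphic
segment), (c) a barcode matching a known round, (d) Phred >= 20 at every
peptide-encoding base, and (e) the NNK pattern (third base G/T) at every
randomized codon.

Within each round, likely PCR/sequencing error reads are then collapsed: a
sequence is discarded when it lies within Hamming radius 1 of a more prevalent
retained sequence, radius 2 of one >= 100x more prevalent, or radius 3 of one
>= 10,000x more prevalent. Remaining unique DNA sequences are translated with
the standard genetic code, stop-containing peptides dropped, and synonymous
variants merged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .designs import LibraryDesign
from .simulate import SimulatedReadSet, translate_codons

_MIN_PHRED_CHAR = 33 + 20  # Phred-33 encoding of Q20


@dataclass
class RawCountTable:
    """Read counts per unique peptide-encoding DNA sequence within one round."""

    round: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())


def read_fastq(path):
    """Yield (sequence, quality) pairs from a 4-line Phred-33 FASTQ file."""
    with open(path) as fh:
        for _title, seq, qual in FastqGeneralIterator(fh):
            yield seq, qual


def filter_reads(records, design: LibraryDesign,
                 round_hint: int | None = None):
    """Run the filter cascade and tabulate kept reads per round.

    Parameters
    ----------
    records : iterable of (sequence, quality) pairs (Phred-33), or a
        SimulatedReadSet.
    design : the library design defining constants, barcodes, NNK layout.
    round_hint : if given, reads are pre-demultiplexed and the barcode check
        assigns all kept reads to this round (the barcode must still match).

    Returns
    -------
    (tables, attrition) : dict round -> RawCountTable, and a per-stage
    attrition report (counts of reads dropped at each filter).
    """
    if isinstance(records, SimulatedReadSet):
        records = records.records
    bl = design.barcode_length
    c5 = design.constant5_dna
    c3 = design.constant3_dna
    pep_start = bl + len(c5)
    pep_len_nt = 3 * design.peptide_length
    pep_end = pep_start + pep_len_nt
    expected_len = design.read_length
    rs = design.randomized_slice
    # third-base offsets of randomized codons within the peptide-encoding region
    nnk_third = np.array([3 * i + 2 for i in range(rs.start, rs.stop)])

    barcode_round = {bc: r for r, bc in design.barcode_by_round.items()}
    attrition = Counter()
    kept: dict[int, Counter] = {}

    seqs, quals, rounds = [], [], []
    for seq, qual in records:
        attrition["total"] += 1
        if len(seq) != len(qual):
            raise ValueError("malformed FASTQ record: sequence/quality length mismatch")
        if len(seq) != expected_len:
            attrition["bad_length"] += 1
            continue
        rnd = barcode_round.get(seq[:bl])
        if rnd is None or (round_hint is not None and rnd != round_hint):
            attrition["bad_barcode"] += 1
            continue
        if seq[bl:pep_start] != c5 or seq[pep_end:] != c3:
            attrition["bad_constant"] += 1
            continue
        seqs.append(seq[pep_start:pep_end])
        quals.append(qual[pep_start:pep_end])
        rounds.append(rnd)

    if seqs:
        n = len(seqs)
        qarr = np.frombuffer("".join(quals).encode(), dtype=np.uint8).reshape(n, pep_len_nt)
        ok_q = (qarr >= _MIN_PHRED_CHAR).all(axis=1)
        sarr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n, pep_len_nt)
        third = sarr[:, nnk_third]
        ok_nnk = ((third == ord("G")) | (third == ord("T"))).all(axis=1)
        attrition["low_quality"] += int((~ok_q).sum())
        attrition["bad_nnk"] += int((ok_q & ~ok_nnk).sum())
        ok = ok_q & ok_nnk
        rounds = np.asarray(rounds)
        for i in np.flatnonzero(ok):
            kept.setdefault(int(rounds[i]), Counter())[seqs[i]] += 1
        attrition["kept"] += int(ok.sum())

    tables = {r: RawCountTable(round=r, counts=dict(c)) for r, c in sorted(kept.items())}
    return tables, dict(attrition)


def _hamming1_neighbors(seq: bytes):
    """All sequences at Hamming distance exactly 1 (ACGT alphabet)."""
    for i in range(len(seq)):
        orig = seq[i]
        for b in b"ACGT":
            if b != orig:
                yield seq[:i] + bytes([b]) + seq[i + 1:]


def collapse_errors(table: RawCountTable,
                    compare_retained_only: bool = True) -> RawCountTable:
    """Discard likely PCR/read-error sequences within one round.

    Sequences are processed in descending count order (ties broken
    lexicographically). A sequence ``s`` is discarded iff some previously
    retained (or, with ``compare_retained_only=False``, any more prevalent)
    sequence ``t`` with ``count(t) > count(s)`` satisfies one of:

    * Hamming(s, t) <= 1,
    * Hamming(s, t) <= 2 and count(t) >= 100 * count(s),
    * Hamming(s, t) <= 3 and count(t) >= 10,000 * count(s).
    """
    if not compare_retained_only:
        return _collapse_all_pairs_mode(table)
    items = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    retained: dict[bytes, int] = {}
    # parallel arrays (descending count order) for the radius-2/3 prevalence gates
    ret_counts: list[int] = []
    ret_arrays: list[np.ndarray] = []
    out: dict[str, int] = {}

    for seq_str, c in items:
        s = seq_str.encode()
        discard = False
        # radius 1: enumerate neighbors, look up more prevalent retained sequences
        for nb in _hamming1_neighbors(s):
            t_count = retained.get(nb)
            if t_count is not None and t_count > c:
                discard = True
                break
        if not discard and ret_counts and ret_counts[0] >= 100 * c:
            # radius 2/3: brute-force Hamming against the (few) retained
            # sequences prevalent enough to trigger the 100x / 10,000x gates
            counts_arr = np.asarray(ret_counts)
            k = int(np.searchsorted(-counts_arr, -(100 * c), side="right"))
            if k:
                sa = np.frombuffer(s, dtype=np.uint8)
                block = np.stack(ret_arrays[:k])
                d = (block != sa).sum(axis=1)
                cc = counts_arr[:k]
                hit = ((d <= 2) & (cc >= 100 * c) & (cc > c)) | \
                      ((d <= 3) & (cc >= 10_000 * c) & (cc > c))
                if hit.any():
                    discard = True
        if not discard:
            retained[s] = c
            ret_counts.append(c)
            ret_arrays.append(np.frombuffer(s, dtype=np.uint8))
            out[seq_str] = c

    return RawCountTable(round=table.round, counts=out)


def _collapse_all_pairs_mode(table: RawCountTable) -> RawCountTable:
    """Variant comparing against all more prevalent sequences (config switch)."""
    items = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    seqs = [k.encode() for k, _ in items]
    counts = np.array([v for _, v in items])
    arrs = np.frombuffer(b"".join(seqs), dtype=np.uint8).reshape(len(seqs), -1)
    out = {}
    for i, (seq_str, c) in enumerate(items):
        prev = counts[:i] > c
        if prev.any():
            d = (arrs[:i][prev] != arrs[i]).sum(axis=1)
            cc = counts[:i][prev]
            hit = (d <= 1) | ((d <= 2) & (cc >= 100 * c)) | ((d <= 3) & (cc >= 10_000 * c))
            if hit.any():
                continue
        out[seq_str] = int(c)
    return RawCountTable(round=table.round, counts=out)


def translate_and_tabulate(tables: dict[int, RawCountTable],
                           design: LibraryDesign) -> pd.DataFrame:
    """Translate collapsed DNA tables into a per-round peptide table.

    Standard genetic code; DNA whose peptide region encodes a stop is dropped;
    synonymous variants of one peptide are merged (read counts summed).

    Returns a DataFrame with columns ``peptide``, ``reads_r{r}`` for every
    round present, and ``final_round`` (max round in which the peptide was
    observed).
    """
    rounds = sorted(tables)
    pep_counts: dict[str, dict[int, int]] = {}
    for r in rounds:
        tab = tables[r]
        if not tab.counts:
            continue
        dnas = list(tab.counts.keys())
        counts = list(tab.counts.values())
        if any(len(d) % 3 for d in dnas):
            raise ValueError("frame error: dna length not divisible by 3")
        n = len(dnas)
        arr = np.frombuffer("".join(dnas).encode(), dtype=np.uint8).reshape(n, -1)
        aa = translate_codons(arr)
        has_stop = (aa == ord("*")).any(axis=1)
        L = aa.shape[1]
        peptides = [b.decode() for b in aa.view(f"S{L}").ravel()]
        for pep, c, stop in zip(peptides, counts, has_stop):
            if stop:
                continue
            pep_counts.setdefault(pep, {})[r] = pep_counts.setdefault(pep, {}).get(r, 0) + c

    rows = []
    for pep, by_round in pep_counts.items():
        row = {"peptide": pep}
        for r in rounds:
            row[f"reads_r{r}"] = by_round.get(r, 0)
        row["final_round"] = max(by_round)
        rows.append(row)
    cols = ["peptide"] + [f"reads_r{r}" for r in rounds] + ["final_round"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values("peptide", ignore_index=True)


def process_rounds(readsets, design: LibraryDesign,
                   compare_retained_only: bool = True):
    """Full pipeline: filter -> collapse per round -> translate/tabulate.

    ``readsets`` is an iterable of SimulatedReadSet or (seq, qual) iterables.
    Returns (peptide_table, attrition_by_stage).
    """
    tables: dict[int, RawCountTable] = {}
    attrition_total = Counter()
    for rs in readsets:
        t, att = filter_reads(rs, design)
        attrition_total.update(att)
        for r, tab in t.items():
            if r in tables:
                merged = Counter(tables[r].counts)
                merged.update(tab.counts)
                tables[r] = RawCountTable(r, dict(merged))
            else:
                tables[r] = tab
    collapsed = {}
    for r, tab in tables.items():
        if compare_retained_only:
            collapsed[r] = collapse_errors(tab)
        else:
            collapsed[r] = _collapse_all_pairs_mode(tab)
        attrition_total[f"collapsed_r{r}"] = len(tab.counts) - len(collapsed[r].counts)
    table = translate_and_tabulate(collapsed, design)
    return table, dict(attrition_total)


def peptides_in_round(table: pd.DataFrame, r: int) -> list[str]:
    """Unique peptides observed (reads > 0) in round ``r``."""
    return table.loc[table[f"reads_r{r}"] > 0, "peptide"].tolist()


def naive_only_peptides(table: pd.DataFrame) -> list[str]:
    """Peptides seen in the unselected library (round 0) and never after."""
    return table.loc[table["final_round"] == 0, "peptide"].tolist()


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
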