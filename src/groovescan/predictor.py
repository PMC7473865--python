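"""Round-weighted binding predictors with NN-Align-style register scanning.

Training examples from yeast-display selections carry a target value between
0 and 1 that increases with the final round of selection in which the peptide
was observed (linear map ``final_round / R``); peptides seen only in the
unselected library are the negatives. MS-style positive sets are paired 1:1
with scrambles of themselves as negatives.

Each ensemble member is a single-hidden-layer feed-forward network trained by
full-batch Adam on (encoded 9mer core [+ flank summary features], target)
pairs; during training the core offset of each example is re-chosen as the
max-scoring window under the current network (register scanning). The
ensemble prediction is the mean member output, and percent ranks are
calibrated against scores of 50,000 background-frequency random 15mers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .designs import AA_INDEX, AA_ORDER, LibraryDesign
from .enrichment import random_peptides, uniprot_background
from .simulate import encode_peptides

CORE_LEN = 9


def _blosum50_rows() -> np.ndarray:
    """(20, 20) BLOSUM50 rows over AA_ORDER, scaled to roughly unit range."""
    mat = substitution_matrices.load("BLOSUM50")
    out = np.empty((20, 20))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            out[i, j] = mat[a, b]
    return out / 10.0


_ENCODERS: dict[str, np.ndarray] = {
    "sparse": np.eye(20),
    "blosum50": _blosum50_rows(),
}


@dataclass
class TrainingExample:
    peptide: str
    target: float
    origin: str  # yeast_round_r, naive_only, ms_positive, ms_scrambled


@dataclass
class TrainConfig:
    """Member grid and optimizer settings (desk-scale defaults exposed)."""

    hidden: tuple[int, ...] = (10, 40)
    encodings: tuple[str, ...] = ("sparse", "blosum50")
    n_partitions: int = 5
    n_seeds: int = 2
    use_pfr: bool = False          # flank summary features (13mer-library models)
    lr: float = 1.0                # full-batch backprop step (gradient is /n)
    momentum: float = 0.9
    max_epochs: int = 500
    patience: int = 20
    rescan_every: int = 10

    @classmethod
    def small(cls, use_pfr: bool = False) -> "TrainConfig":
        """Reduced grid for quick desk-scale training runs."""
        return cls(hidden=(16,), encodings=("sparse", "blosum50"),
                   n_partitions=2, n_seeds=1, use_pfr=use_pfr,
                   max_epochs=150, patience=10)


@dataclass
class _Member:
    encoding: str
    width: int
    partition: int
    seed: int
    W1: np.ndarray = None
    b1: np.ndarray = None
    w2: np.ndarray = None
    b2: float = 0.0


@dataclass
class PredictorEnsemble:
    members: list[_Member]
    use_pfr: bool
    rank_calibration: np.ndarray | None = None  # sorted ascending
    calibration_seed: int | None = None
    config: dict = field(default_factory=dict)


def make_training_set(table: pd.DataFrame, design: LibraryDesign,
                      cap: int = 80_000, seed: int = 0) -> list[TrainingExample]:
    """Round-weighted training set from a per-round peptide table.

    Emits only the randomized residues of each peptide. Positives (observed
    in round >= 1) get target ``final_round / R``; peptides seen only in the
    unselected library get target 0. When the table exceeds ``cap`` rows, a
    seeded stratified subsample preserves the per-round proportions.
    """
    rounds = sorted(int(c.split("_r")[1]) for c in table.columns if c.startswith("reads_r"))
    R = max(rounds)
    if R < 1:
        raise ValueError("table must contain at least one selection round")
    if not (table["final_round"] == 0).any():
        raise ValueError("no negative examples: no naive-only peptides in table")
    rng = np.random.default_rng(seed)
    rs = design.randomized_slice

    frames = []
    for fr, grp in table.groupby("final_round"):
        frames.append((int(fr), grp))
    total = len(table)
    examples: list[TrainingExample] = []
    for fr, grp in frames:
        n_take = len(grp)
        if total > cap:
            n_take = max(1, int(round(len(grp) * cap / total)))
            pick = rng.choice(len(grp), size=n_take, replace=False)
            grp = grp.iloc[np.sort(pick)]
        target = fr / R
        origin = "naive_only" if fr == 0 else f"yeast_round_{fr}"
        for pep in grp["peptide"]:
            examples.append(TrainingExample(pep[rs], target, origin))
    return examples


def make_training_set_ms(positives, seed: int = 0) -> list[TrainingExample]:
    """MS-style set: each positive (target 1) paired with one scramble (target 0)."""
    positives = list(dict.fromkeys(positives))
    if not positives:
        raise ValueError("no positive peptides")
    rng = np.random.default_rng(seed)
    out: list[TrainingExample] = []
    for pep in positives:
        if len(pep) < 2:
            raise ValueError("cannot scramble a length-1 peptide")
        out.append(TrainingExample(pep, 1.0, "ms_positive"))
        if len(set(pep)) == 1:
            raise ValueError(f"cannot scramble homopolymer peptide {pep!r}")
        while True:
            perm = rng.permutation(len(pep))
            scr = "".join(pep[i] for i in perm)
            if scr != pep:
                break
        out.append(TrainingExample(scr, 0.0, "ms_scrambled"))
    return out


# ---------------------------------------------------------------------------
# feature encoding

def _n_features(encoding: str, use_pfr: bool) -> int:
    return CORE_LEN * 20 + (2 * 20 + 2 if use_pfr else 0)


def _encode_windows(pep_idx: np.ndarray, encoding: str, use_pfr: bool) -> np.ndarray:
    """(n_peptides, n_windows, features) window encodings of same-length peptides."""
    enc = _ENCODERS[encoding]
    n, L = pep_idx.shape
    n_win = L - CORE_LEN + 1
    rows = enc[pep_idx]  # (n, L, 20)
    out = np.empty((n, n_win, _n_features(encoding, use_pfr)), dtype=np.float32)
    for o in range(n_win):
        core = rows[:, o:o + CORE_LEN, :].reshape(n, -1)
        if not use_pfr:
            out[:, o, :] = core
            continue
        lo = max(0, o - 2)
        left = rows[:, lo:o, :]
        left_mean = left.mean(axis=1) if left.shape[1] else np.zeros((n, 20))
        hi = min(L, o + CORE_LEN + 2)
        right = rows[:, o + CORE_LEN:hi, :]
        right_mean = right.mean(axis=1) if right.shape[1] else np.zeros((n, 20))
        flank_feats = np.stack([
            np.full(n, min(o, 2) / 2.0),
            np.full(n, min(L - CORE_LEN - o, 2) / 2.0),
        ], axis=1)
        out[:, o, :] = np.concatenate([core, left_mean, right_mean, flank_feats], axis=1)
    return out


# ---------------------------------------------------------------------------
# network

def _forward(X: np.ndarray, m: _Member) -> np.ndarray:
    h = np.tanh(X @ m.W1 + m.b1)
    z = h @ m.w2 + m.b2
    return 1.0 / (1.0 + np.exp(-z))


def _train_member(X_win: np.ndarray, targets: np.ndarray, train_idx: np.ndarray,
                  val_idx: np.ndarray, member: _Member, cfg: TrainConfig,
                  rng: np.random.Generator) -> _Member:
    """Full-batch backprop (momentum) with register scanning and early stopping.

    Plain gradient descent is used deliberately: adaptive per-parameter
    optimizers equalize the learning speed of signal and memorization
    directions on sparse one-hot features, hurting generalization on the
    small, wide training matrices typical here.
    """
    n_feat = X_win.shape[2]
    h = member.width
    member.W1 = rng.normal(0, 0.1, size=(n_feat, h))
    member.b1 = np.zeros(h)
    member.w2 = rng.normal(0, 0.1, size=h)
    member.b2 = 0.0

    n_win = X_win.shape[1]
    sel = np.zeros(len(targets), dtype=int)

    vel = [np.zeros((n_feat, h)), np.zeros(h), np.zeros(h), 0.0]
    best_val = np.inf
    best = None
    wait = 0

    def current_X(idx_set):
        return X_win[idx_set, sel[idx_set], :]

    for epoch in range(cfg.max_epochs):
        if n_win > 1 and epoch % cfg.rescan_every == 0:
            # register scanning: pick each example's max-scoring window
            flat = X_win.reshape(-1, n_feat)
            outs = _forward(flat, member).reshape(-1, n_win)
            sel = outs.argmax(axis=1)

        X = current_X(train_idx)
        t = targets[train_idx]
        htan = np.tanh(X @ member.W1 + member.b1)
        z = htan @ member.w2 + member.b2
        y = 1.0 / (1.0 + np.exp(-z))
        err = y - t
        dz = err * y * (1 - y) / len(t)
        gw2 = htan.T @ dz
        gb2 = dz.sum()
        dh = np.outer(dz, member.w2) * (1 - htan ** 2)
        gW1 = X.T @ dh
        gb1 = dh.sum(axis=0)

        for i, g in enumerate((gW1, gb1, gw2, gb2)):
            vel[i] = cfg.momentum * vel[i] - cfg.lr * g
        member.W1 += vel[0]
        member.b1 += vel[1]
        member.w2 += vel[2]
        member.b2 += vel[3]

        Xv = current_X(val_idx)
        val_mse = float(np.mean((_forward(Xv, member) - targets[val_idx]) ** 2))
        if val_mse < best_val - 1e-7:
            best_val = val_mse
            best = (member.W1.copy(), member.b1.copy(), member.w2.copy(), member.b2)
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break

    if best is not None:
        member.W1, member.b1, member.w2, member.b2 = best
    return member


def train_ensemble(examples: list[TrainingExample], config: TrainConfig | None = None,
                   seed: int = 0) -> PredictorEnsemble:
    """Train the member grid (encodings x widths x CV partitions x seeds)."""
    if config is None:
        config = TrainConfig()
    targets = np.array([e.target for e in examples])
    if not ((targets > 0).any() and (targets == 0).any()):
        raise ValueError("examples must contain both positive and zero targets")
    if not (config.hidden and config.encodings and config.n_partitions and config.n_seeds):
        raise ValueError("empty ensemble: degenerate member grid")
    lens = {len(e.peptide) for e in examples}
    if len(lens) != 1:
        raise ValueError("ragged peptide set: training peptides differ in length")
    peptides = [e.peptide for e in examples]
    pep_idx = encode_peptides(peptides)

    rng_part = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    perm = rng_part.permutation(len(examples))
    folds = np.array_split(perm, config.n_partitions)

    X_by_enc = {enc: _encode_windows(pep_idx, enc, config.use_pfr)
                for enc in config.encodings}

    members: list[_Member] = []
    ss = np.random.SeedSequence(seed + 1)
    grid = [(w, enc, p, s)
            for w in config.hidden for enc in config.encodings
            for p in range(config.n_partitions) for s in range(config.n_seeds)]
    children = ss.spawn(len(grid))
    for (w, enc, p, s), child in zip(grid, children):
        val_idx = folds[p]
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != p])
        member = _Member(encoding=enc, width=w, partition=p, seed=s)
        rng = np.random.default_rng(child)
        members.append(_train_member(X_by_enc[enc], targets, train_idx, val_idx,
                                     member, config, rng))
    return PredictorEnsemble(members=members, use_pfr=config.use_pfr,
                             config=asdict(config))


def predict_many(ensemble: PredictorEnsemble, peptides) -> pd.DataFrame:
    """Ensemble scores and modal best core offsets for same-length peptides."""
    peptides = list(peptides)
    if not peptides:
        return pd.DataFrame(columns=["peptide", "score", "core_offset"])
    if min(len(p) for p in peptides) < CORE_LEN:
        raise ValueError("too short: peptides must be >= 9 residues")
    lens = {len(p) for p in peptides}
    if len(lens) != 1:
        raise ValueError("ragged peptide set: peptides differ in length")
    pep_idx = encode_peptides(peptides)
    n = len(peptides)
    n_win = pep_idx.shape[1] - CORE_LEN + 1
    scores = np.zeros(n)
    offset_votes = np.zeros((n, n_win), dtype=int)
    cache: dict[str, np.ndarray] = {}
    for m in ensemble.members:
        if m.encoding not in cache:
            cache[m.encoding] = _encode_windows(pep_idx, m.encoding, ensemble.use_pfr)
        X = cache[m.encoding]
        outs = _forward(X.reshape(-1, X.shape[2]), m).reshape(n, n_win)
        scores += outs.max(axis=1)
        offset_votes[np.arange(n), outs.argmax(axis=1)] += 1
    scores /= len(ensemble.members)
    offsets = offset_votes.argmax(axis=1)  # modal window; ties -> lowest offset
    return pd.DataFrame({"peptide": peptides, "score": scores,
                         "core_offset": offsets.astype(int)})


def predict(ensemble: PredictorEnsemble, peptide: str,
            invert: bool = False) -> tuple[float, int]:
    """Score one peptide: (mean member score in [0,1], modal best core offset).

    Higher score = stronger predicted binding; ``invert`` returns 1 - score
    for comparability with affinity-style outputs where lower is stronger.
    """
    df = predict_many(ensemble, [peptide])
    score = float(df["score"].iloc[0])
    return (1.0 - score if invert else score), int(df["core_offset"].iloc[0])


def calibrate(ensemble: PredictorEnsemble, n: int = 50_000, length: int = 15,
              seed: int = 0) -> PredictorEnsemble:
    """Populate the percent-rank calibration with random background 15mers."""
    peps = random_peptides(n, length, uniprot_background(), seed=seed)
    scores = predict_many(ensemble, peps)["score"].to_numpy()
    ensemble.rank_calibration = np.sort(scores)
    ensemble.calibration_seed = seed
    return ensemble


def percent_rank(ensemble: PredictorEnsemble, score: float) -> float:
    """Percent of calibration scores >= score (lower rank = stronger binder)."""
    cal = ensemble.rank_calibration
    if cal is None or len(cal) == 0:
        raise ValueError("uncalibrated ensemble")
    n_ge = len(cal) - np.searchsorted(cal, score, side="left")
    return 100.0 * n_ge / len(cal)


def save_ensemble(ensemble: PredictorEnsemble, path) -> None:
    d = {
        "use_pfr": ensemble.use_pfr,
        "config": ensemble.config,
        "calibration_seed": ensemble.calibration_seed,
        "rank_calibration": (None if ensemble.rank_calibration is None
                             else ensemble.rank_calibration.tolist()),
        "members": [
            {"encoding": m.encoding, "width": m.width, "partition": m.partition,
             "seed": m.seed, "W1": m.W1.tolist(), "b1": m.b1.tolist(),
             "w2": m.w2.tolist(), "b2": float(m.b2)}
            for m in ensemble.members
        ],
    }
    with open(path, "w") as fh:
        json.dump(d, fh)


def load_ensemble(path) -> PredictorEnsemble:
    with open(path) as fh:
        d = json.load(fh)
    members = [
        _Member(encoding=m["encoding"], width=m["width"], partition=m["partition"],
                seed=m["seed"], W1=np.array(m["W1"]), b1=np.array(m["b1"]),
                w2=np.array(m["w2"]), b2=m["b2"])
        for m in d["members"]
    ]
    cal = d["rank_calibration"]
    return PredictorEnsemble(
        members=members, use_pfr=d["use_pfr"],
        rank_calibration=None if cal is None else np.array(cal),
        calibration_seed=d["calibration_seed"], config=d["config"],
    )
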