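"""Expected Pattern Effect (EPE) and Differential EPE (DEPE).

The effect of a DNA pattern p (a motif, motif pair, or spaced motif
grammar) on a model's class-c output is estimated by inserting p into
each of M background sequences x_m drawn from the natural sequence
distribution and comparing predictions with and without the insertion:

    alpha_c^p = (1/M) * sum_m f_c(x_m^p) / f_c(x_m)

alpha > 1 means the pattern increases predicted activity for class c.
Using a ratio rather than a difference makes the effect comparable
across classes whose baseline prediction levels differ (e.g. under
class imbalance). Significance comes from the Wilcoxon signed-rank
statistic of the per-background log2 ratios,

    W = (1/M) * sum_m sign(log2 ratio_m) * R_m

with R_m the rank of the absolute log2 ratio; note the normalization by
the full M (zeros are dropped before ranking but still count in M), so
|W| <= (M+1)/2. The differential effect between classes c1 and c2 is
the mean per-background difference of log2 ratios (DEPE), tested the
same way.

The difference-based estimator of Global Importance Analysis,
(1/M) sum f(x^p) - f(x), is provided as a comparator for robustness
studies; it is not used by the screens.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import LabeledDataset, read_fasta, write_fasta
from .model import ModelEnsemble
from .motifs import PWM, Pattern, consensus, paired_pattern, sample_site

#: predictions are clipped to [EPS, 1-EPS] before ratios and logs
EPS = 1e-6

#: default number of background sequences
DEFAULT_M = 24

BACKGROUND_SOURCES = (
    "closed_random", "open_random", "promoter_closed", "promoter_open",
    "user", "synthetic",
)


@dataclass
class BackgroundSet:
    """The M sequences approximating the sequence distribution D."""

    sequences: list[str]
    source: str = "user"
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("background set needs at least 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("background sequences must all have equal length")
        if self.source not in BACKGROUND_SOURCES:
            raise ValueError(f"unknown background source {self.source!r}")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def window_length(self) -> int:
        return len(self.sequences[0])

    @classmethod
    def from_fasta(cls, path, source: str = "user") -> "BackgroundSet":
        return cls(sequences=list(read_fasta(path).values()), source=source)

    def to_fasta(self, path) -> None:
        write_fasta(path, {f"bg_{i}": s for i, s in enumerate(self.sequences)})


def default_backgrounds() -> BackgroundSet:
    """The packaged default background set (24 synthetic 100-nt sequences)."""
    ref = importlib.resources.files("motifeffect") / "data" / "backgrounds_synthetic.fa"
    with importlib.resources.as_file(ref) as path:
        return BackgroundSet.from_fasta(path, source="synthetic")


@dataclass
class EPEResult:
    """Expected Pattern Effect of one pattern on one class."""

    pattern_id: str
    class_name: str
    alpha: float
    log2_ratios: np.ndarray
    W: float
    p_value: float
    p_adjusted: float
    M: int
    n_zero_dropped: int


@dataclass
class DEPEResult:
    """Differential Expected Pattern Effect of one pattern between two classes."""

    pattern_id: str
    class_pair: tuple[str, str]
    depe: float
    per_seq: np.ndarray
    W: float
    p_value: float
    p_adjusted: float
    M: int
    n_zero_dropped: int


# ---------------------------------------------------------------------------
# pattern insertion
# ---------------------------------------------------------------------------


def insert_pattern(background: str, pattern: Pattern, position: int | None = None) -> str:
    """Substitute a pattern into a background sequence (length-preserving).

    Default position centers the pattern: floor((L - len(template))/2).
    ``*`` template positions keep the background base.
    """
    L, T = len(background), len(pattern.template)
    if T > L:
        raise ValueError(f"pattern {pattern.id} ({T} nt) longer than background ({L} nt)")
    if position is None:
        position = (L - T) // 2
    if position < 0 or position + T > L:
        raise ValueError(f"insertion position {position} out of range for {T} nt in {L} nt")
    out = list(background)
    for j, ch in enumerate(pattern.template):
        if ch != "*":
            out[position + j] = ch
    return "".join(out)


# ---------------------------------------------------------------------------
# signed-rank statistic
# ---------------------------------------------------------------------------


def _exact_signed_rank_p(ranks: np.ndarray, observed: float) -> float:
    """Exact two-sided P(|sum of +-ranks| >= |observed|) under random signs.

    Tie-averaged ranks are multiples of 1/2; doubling makes them
    integers, so the null distribution of the doubled signed-rank sum
    is enumerated by dynamic programming over 2^n equally likely sign
    assignments.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    size = 2 * total + 1  # sums shifted by +total -> index range [0, 2*total]
    counts = np.zeros(size)
    counts[total] = 1.0
    for r in r2:
        nxt = np.zeros(size)
        nxt[r:] += counts[: size - r]
        nxt[: size - r] += counts[r:]
        counts = nxt
    sums = np.arange(-total, total + 1)
    threshold = abs(2 * observed) - 1e-9
    return float(counts[np.abs(sums) >= threshold].sum() / counts.sum())


def signed_rank(values) -> tuple[float, float]:
    """Normalized Wilcoxon signed-rank statistic and two-sided p-value.

    Zeros are dropped before ranking but the normalization uses the
    original count M, so W = (1/M) sum sign(v)*R with tie-averaged
    ranks R over the non-zero |v|. The p-value uses the exact null
    (sign-flip enumeration, tie-aware) for up to 25 non-zero values and
    a normal approximation with continuity correction above. All-zero
    input gives (0, 1): no evidence, not an error.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("signed_rank requires at least one value")
    M = v.size
    nz = v[v != 0]
    if nz.size == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(nz))
    s_obs = float(np.sum(np.sign(nz) * ranks))
    if nz.size <= 25:
        p = _exact_signed_rank_p(ranks, s_obs)
    else:
        # normal approximation on the signed-rank sum: mean 0, var sum(r^2)
        sd = float(np.sqrt(np.sum(ranks**2)))
        z = max(abs(s_obs) - 1.0, 0.0) / sd  # continuity correction: step size 2
        p = float(2 * stats.norm.sf(z))
    return s_obs / M, min(p, 1.0)


# ---------------------------------------------------------------------------
# effect estimators
# ---------------------------------------------------------------------------


def _predict_pairs(
    ensemble: ModelEnsemble,
    backgrounds: BackgroundSet,
    pattern: Pattern,
    position: int | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Clipped predictions for backgrounds and pattern-inserted backgrounds."""
    inserted = [insert_pattern(s, pattern, position) for s in backgrounds.sequences]
    probs = ensemble.predict(backgrounds.sequences + inserted)
    probs = np.clip(probs, EPS, 1 - EPS)
    M = len(backgrounds)
    return probs[:M], probs[M:]


def epe(
    ensemble: ModelEnsemble,
    backgrounds: BackgroundSet,
    pattern: Pattern,
    class_name: str,
    position: int | None = None,
    both_strands: bool = False,
    n_tests: int = 1,
) -> EPEResult:
    """Expected Pattern Effect of ``pattern`` on class ``class_name``.

    With ``both_strands`` the larger of the forward and
    reverse-complement per-background ratios is used.
    """
    ci = ensemble.class_names.index(class_name)
    base, ins = _predict_pairs(ensemble, backgrounds, pattern, position)
    ratios = ins[:, ci] / base[:, ci]
    if both_strands:
        _, ins_rc = _predict_pairs(
            ensemble, backgrounds, pattern.reverse_complement(), position
        )
        ratios = np.maximum(ratios, ins_rc[:, ci] / base[:, ci])
    log2_ratios = np.log2(ratios)
    W, p = signed_rank(log2_ratios)
    return EPEResult(
        pattern_id=pattern.id,
        class_name=class_name,
        alpha=float(ratios.mean()),
        log2_ratios=log2_ratios,
        W=W,
        p_value=p,
        p_adjusted=min(1.0, p * n_tests),
        M=len(backgrounds),
        n_zero_dropped=int((log2_ratios == 0).sum()),
    )


def depe(
    ensemble: ModelEnsemble,
    backgrounds: BackgroundSet,
    pattern: Pattern,
    class1: str,
    class2: str,
    position: int | None = None,
    n_tests: int = 1,
) -> DEPEResult:
    """Differential Expected Pattern Effect between two classes.

    Positive DEPE means the pattern favors ``class1``; the result is
    exactly antisymmetric in the class order on identical backgrounds.
    """
    if class1 == class2:
        raise ValueError("DEPE requires two distinct classes")
    c1 = ensemble.class_names.index(class1)
    c2 = ensemble.class_names.index(class2)
    base, ins = _predict_pairs(ensemble, backgrounds, pattern, position)
    diffs = np.log2(ins[:, c1] / base[:, c1]) - np.log2(ins[:, c2] / base[:, c2])
    W, p = signed_rank(diffs)
    return DEPEResult(
        pattern_id=pattern.id,
        class_pair=(class1, class2),
        depe=float(diffs.mean()),
        per_seq=diffs,
        W=W,
        p_value=p,
        p_adjusted=min(1.0, p * n_tests),
        M=len(backgrounds),
        n_zero_dropped=int((diffs == 0).sum()),
    )


def depe_one_vs_rest(
    ensemble: ModelEnsemble,
    backgrounds: BackgroundSet,
    pattern: Pattern,
    class_name: str,
    position: int | None = None,
    n_tests: int = 1,
) -> DEPEResult:
    """DEPE of one class against the mean prediction of all other classes."""
    ci = ensemble.class_names.index(class_name)
    rest = [j for j in range(len(ensemble.class_names)) if j != ci]
    if not rest:
        raise ValueError("one-vs-rest needs at least two classes")
    base, ins = _predict_pairs(ensemble, backgrounds, pattern, position)
    base_rest = np.clip(base[:, rest].mean(axis=1), EPS, 1 - EPS)
    ins_rest = np.clip(ins[:, rest].mean(axis=1), EPS, 1 - EPS)
    diffs = np.log2(ins[:, ci] / base[:, ci]) - np.log2(ins_rest / base_rest)
    W, p = signed_rank(diffs)
    return DEPEResult(
        pattern_id=pattern.id,
        class_pair=(class_name, "rest"),
        depe=float(diffs.mean()),
        per_seq=diffs,
        W=W,
        p_value=p,
        p_adjusted=min(1.0, p * n_tests),
        M=len(backgrounds),
        n_zero_dropped=int((diffs == 0).sum()),
    )


def gia_effect(
    ensemble: ModelEnsemble,
    backgrounds: BackgroundSet,
    pattern: Pattern,
    class_name: str,
    position: int | None = None,
) -> float:
    """Difference-based pattern effect, (1/M) sum f(x^p) - f(x).

    The Global Importance Analysis estimator; kept as a comparator for
    class-imbalance robustness studies only.
    """
    ci = ensemble.class_names.index(class_name)
    base, ins = _predict_pairs(ensemble, backgrounds, pattern, position)
    return float((ins[:, ci] - base[:, ci]).mean())


# ---------------------------------------------------------------------------
# screens and scans
# ---------------------------------------------------------------------------


def _adjust(pvals: np.ndarray, method: str, n_tests: int) -> np.ndarray:
    if method == "bonferroni":
        return np.minimum(1.0, pvals * n_tests)
    if method == "bh":
        order = np.argsort(pvals)
        adj = np.empty_like(pvals)
        m = len(pvals)
        running = 1.0
        for rank_from_top in range(m - 1, -1, -1):
            i = order[rank_from_top]
            running = min(running, pvals[i] * m / (rank_from_top + 1))
            adj[i] = running
        return adj
    raise ValueError(f"unknown correction {method!r}")


def _as_patterns(
    motif_db: list[PWM] | list[Pattern], reduction: str, seed: int
) -> list[Pattern]:
    patterns = []
    for k, m in enumerate(motif_db):
        if isinstance(m, Pattern):
            patterns.append(m)
        elif reduction == "consensus":
            patterns.append(consensus(m))
        elif reduction == "sample":
            patterns.append(sample_site(m, seed + k))
        else:
            raise ValueError(f"unknown motif reduction {reduction!r}")
    return patterns


def motif_screen(
    ensemble: ModelEnsemble,
    backgrounds: BackgroundSet,
    motif_db: list[PWM] | list[Pattern],
    classes: list[str] | None = None,
    class_pairs: list[tuple[str, str]] | None = None,
    one_vs_rest: bool = False,
    reduction: str = "consensus",
    seed: int = 0,
    position: int | None = None,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Screen a motif panel for per-class EPEs and/or class-pair DEPEs.

    One row per (pattern, class) and per (pattern, class pair). The
    multiple-testing divisor is the number of patterns screened (not
    patterns x comparisons), applied within each comparison; Bonferroni
    by default, Benjamini-Hochberg with ``correction="bh"``.
    """
    if not motif_db:
        raise ValueError("motif_db must be non-empty")
    patterns = _as_patterns(motif_db, reduction, seed)
    K = len(patterns)
    rows: list[dict] = []
    if one_vs_rest:
        class_list = classes if classes is not None else list(ensemble.class_names)
        for cname in class_list:
            for pat in patterns:
                r = depe_one_vs_rest(ensemble, backgrounds, pat, cname, position)
                rows.append({
                    "pattern_id": pat.id, "class1": cname, "class2": "rest",
                    "effect": r.depe, "W": r.W, "p_value": r.p_value,
                    "M": r.M, "n_zero_dropped": r.n_zero_dropped,
                    "comparison": f"{cname}_vs_rest", "kind": "depe",
                })
    else:
        for cname in classes or []:
            for pat in patterns:
                r = epe(ensemble, backgrounds, pat, cname, position)
                rows.append({
                    "pattern_id": pat.id, "class1": cname, "class2": "",
                    "effect": r.alpha, "W": r.W, "p_value": r.p_value,
                    "M": r.M, "n_zero_dropped": r.n_zero_dropped,
                    "comparison": cname, "kind": "epe",
                })
        for c1, c2 in class_pairs or []:
            for pat in patterns:
                r = depe(ensemble, backgrounds, pat, c1, c2, position)
                rows.append({
                    "pattern_id": pat.id, "class1": c1, "class2": c2,
                    "effect": r.depe, "W": r.W, "p_value": r.p_value,
                    "M": r.M, "n_zero_dropped": r.n_zero_dropped,
                    "comparison": f"{c1}_vs_{c2}", "kind": "depe",
                })
    if not rows:
        raise ValueError("no classes or class pairs requested")
    table = pd.DataFrame(rows)
    table["p_adjusted"] = np.concatenate([
        _adjust(grp["p_value"].to_numpy(), correction, K)
        for _, grp in table.groupby("comparison", sort=False)
    ])
    return table


def spacing_scan(
    ensemble: ModelEnsemble,
    backgrounds: BackgroundSet,
    motif_a: Pattern | PWM,
    motif_b: Pattern | PWM,
    spacings: list[int],
    class_name: str,
    both_orders: bool = False,
    position: int | None = None,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """EPE of a motif pair as a function of the gap between the motifs.

    Spacer positions are wildcards that keep the background base, so
    the scan isolates the geometric preference. Spacings that make the
    pattern exceed the window are skipped with a warning. Rows are
    sorted by spacing.
    """
    pat_a = consensus(motif_a) if isinstance(motif_a, PWM) else motif_a
    pat_b = consensus(motif_b) if isinstance(motif_b, PWM) else motif_b
    L = backgrounds.window_length
    orders = [(pat_a, pat_b, "ab")] + ([(pat_b, pat_a, "ba")] if both_orders else [])
    rows = []
    for spacing in sorted(spacings):
        if len(pat_a) + spacing + len(pat_b) > L:
            warnings.warn(
                f"spacing {spacing}: pattern exceeds window length {L}; skipped",
                stacklevel=2,
            )
            continue
        for first, second, tag in orders:
            pat = paired_pattern(first, second, spacing)
            r = epe(ensemble, backgrounds, pat, class_name, position)
            rows.append({
                "spacing": spacing, "order": tag, "pattern_id": pat.id,
                "class": class_name, "alpha": r.alpha, "W": r.W,
                "p_value": r.p_value, "M": r.M,
                "n_zero_dropped": r.n_zero_dropped,
            })
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = _adjust(
            table["p_value"].to_numpy(), correction, len(table)
        )
    return table


# ---------------------------------------------------------------------------
# per-base differential importance
# ---------------------------------------------------------------------------


def differential_saliency(
    ensemble: ModelEnsemble, sequence: str, class1: str, class2: str
) -> np.ndarray:
    """Per-base differential importance between two classes.

    The gradient of log f_c1(x) - log f_c2(x) with respect to the
    one-hot input, multiplied elementwise by the input and summed over
    the four channels (gradient x input), averaged over ensemble
    members. Positions driving the class-1-over-class-2 prediction
    score positive.
    """
    c1 = ensemble.class_names.index(class1)
    c2 = ensemble.class_names.index(class2)
    x = ensemble.encode([sequence])
    scores = np.zeros(x.shape[1])
    for member in ensemble.members:
        p = member.predict(x)
        # d/dz of log sigmoid(z) is 1 - sigmoid(z)
        dlogits = np.zeros((1, len(ensemble.class_names)))
        dlogits[0, c1] = 1.0 - p[0, c1]
        dlogits[0, c2] = -(1.0 - p[0, c2])
        grad = member.input_gradient(x, dlogits)
        scores += (grad[0] * x[0]).sum(axis=1)
    return scores / len(ensemble.members)


# ---------------------------------------------------------------------------
# background sampling
# ---------------------------------------------------------------------------


def sample_backgrounds(
    dataset: LabeledDataset,
    selection: str = "closed_random",
    M: int = DEFAULT_M,
    seed: int = 0,
    eligible_mask: np.ndarray | None = None,
) -> BackgroundSet:
    """Draw M background sequences from a labeled dataset without replacement.

    ``closed_random`` draws from windows labeled 0 in every class (the
    default, mirroring closed-chromatin backgrounds); ``open_random``
    from windows labeled 1 in every class. The promoter-restricted
    sources additionally require ``eligible_mask`` marking promoter
    windows. Reproducible for a fixed seed.
    """
    labels = dataset.labels
    if selection in ("closed_random", "promoter_closed"):
        mask = labels.sum(axis=1) == 0
    elif selection in ("open_random", "promoter_open"):
        mask = labels.sum(axis=1) == labels.shape[1]
    elif selection == "user":
        mask = np.ones(len(dataset), dtype=bool)
    else:
        raise ValueError(f"unknown background selection {selection!r}")
    if selection.startswith("promoter"):
        if eligible_mask is None:
            raise ValueError(f"{selection} requires an eligible_mask of promoter windows")
        mask &= np.asarray(eligible_mask, dtype=bool)
    pool = np.flatnonzero(mask)
    if len(pool) < M:
        raise ValueError(
            f"only {len(pool)} eligible sequences for selection {selection!r}, need {M}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=M, replace=False)
    return BackgroundSet(
        sequences=[dataset.sequences[i] for i in chosen],
        source=selection,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def results_to_tsv(results, path) -> None:
    """Write EPE/DEPE results (list of result objects or a DataFrame) as TSV."""
    if isinstance(results, pd.DataFrame):
        results.to_csv(path, sep="\t", index=False)
        return
    rows = []
    for r in results:
        if isinstance(r, EPEResult):
            rows.append({
                "pattern_id": r.pattern_id, "class": r.class_name,
                "effect": r.alpha, "W": r.W, "p_value": r.p_value,
                "p_adjusted": r.p_adjusted, "M": r.M,
                "n_zero_dropped": r.n_zero_dropped,
            })
        else:
            rows.append({
                "pattern_id": r.pattern_id, "class": "|".join(r.class_pair),
                "effect": r.depe, "W": r.W, "p_value": r.p_value,
                "p_adjusted": r.p_adjusted, "M": r.M,
                "n_zero_dropped": r.n_zero_dropped,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
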