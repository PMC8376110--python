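"""Synthetic sequence datasets with known regulatory grammar.

Generates fixed-length DNA windows whose classes are defined by
embedded motif content: each class carries its own motif (or motif
pair at a fixed gap) inserted near the window center in a controllable
fraction of its sequences, on an i.i.d. background of configurable GC
content. Also generates grammar-free background pools, decoy motif
panels, and balanced/imbalanced dataset pairs. Every draw is
reproducible from the spec seed.

Embedded motif instances are sampled from the PWM rather than fixed at
the consensus, so recovering a motif from a trained model is a real
statistical task, not substring matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genomic_io import GenomicRegion, LabeledDataset
from .motifs import PWM, Pattern, consensus, paired_pattern, sample_site

_BASES = np.array(list("ACGT"))


@dataclass
class GrammarSpec:
    """Motif grammar defining one class.

    ``motifs`` holds PWMs (instances sampled per sequence) or fixed
    Patterns. With ``spacing=(a, b, gap)`` the grammar is the pair
    motifs[a]--gap--motifs[b]; otherwise motifs[0] alone is embedded.
    """

    class_name: str
    motifs: list[PWM | Pattern]
    spacing: tuple[int, int, int] | None = None
    embed_prob: float = 0.9
    position_jitter: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.embed_prob <= 1:
            raise ValueError("embed_prob must be in (0, 1]")
        if not self.motifs:
            raise ValueError("grammar needs at least one motif")

    def grammar_length(self) -> int:
        def plen(m):
            return len(m)

        if self.spacing is not None:
            a, b, gap = self.spacing
            return plen(self.motifs[a]) + gap + plen(self.motifs[b])
        return plen(self.motifs[0])

    def instance(self, rng: np.random.Generator) -> Pattern:
        """Draw one concrete pattern instance of the grammar."""

        def draw(m) -> Pattern:
            if isinstance(m, PWM):
                return sample_site(m, int(rng.integers(0, 2**31)))
            return m

        if self.spacing is not None:
            a, b, gap = self.spacing
            return paired_pattern(draw(self.motifs[a]), draw(self.motifs[b]), gap)
        return draw(self.motifs[0])

    def motif_templates(self) -> list[str]:
        """Consensus templates of the grammar motifs (for decoy screening)."""
        return [
            consensus(m).template if isinstance(m, PWM) else m.template
            for m in self.motifs
        ]


@dataclass
class SyntheticSpec:
    """Full recipe for a synthetic labeled dataset."""

    grammars: list[GrammarSpec]
    n_per_class: list[int]
    n_negative: int | None = None  # default: half the mean class count
    window_length: int = 100
    gc: float = 0.5
    decoy_motifs: list[PWM] = field(default_factory=list)
    seed: int = 0
    fake_chroms: list[str] = field(
        default_factory=lambda: ["chr1", "chr2", "chr3", "chr18", "chr19"]
    )

    def __post_init__(self) -> None:
        if len(self.grammars) < 2:
            raise ValueError("need at least 2 classes")
        if len(self.n_per_class) != len(self.grammars):
            raise ValueError("n_per_class must match grammars")
        for g in self.grammars:
            if g.grammar_length() + 2 * g.position_jitter > self.window_length:
                raise ValueError(
                    f"grammar for {g.class_name} does not fit the window at all "
                    "jittered positions"
                )
        names = [g.class_name for g in self.grammars]
        if len(set(names)) != len(names):
            raise ValueError("grammar class names must be unique")

    @property
    def class_names(self) -> list[str]:
        return [g.class_name for g in self.grammars]

    def resolved_n_negative(self) -> int:
        if self.n_negative is not None:
            return self.n_negative
        return int(round(0.5 * float(np.mean(self.n_per_class))))


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _embed(seq: str, pattern: Pattern, position: int) -> str:
    out = list(seq)
    for j, ch in enumerate(pattern.template):
        if ch != "*":
            out[position + j] = ch
    return "".join(out)


def generate_dataset(spec: SyntheticSpec) -> tuple[LabeledDataset, pd.DataFrame]:
    """Generate sequences, labels, provenance, and a ground-truth table.

    The truth table records, per sequence, its class, whether the
    grammar was embedded, the concrete instance, and its start
    position. Provenance chromosomes are assigned round-robin over
    ``fake_chroms`` with window-aligned coordinates, so
    chromosome-held-out splitting is exercised end to end.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.window_length
    C = len(spec.grammars)
    sequences: list[str] = []
    labels: list[np.ndarray] = []
    truth_rows: list[dict] = []

    def add(seq: str, label: np.ndarray, cls: str, embedded: bool,
            pattern_id: str, position) -> None:
        sequences.append(seq)
        labels.append(label)
        truth_rows.append({
            "index": len(sequences) - 1, "class": cls, "embedded": embedded,
            "pattern_id": pattern_id, "position": position,
        })

    for ci, grammar in enumerate(spec.grammars):
        for _ in range(spec.n_per_class[ci]):
            seq = _random_sequence(rng, L, spec.gc)
            label = np.zeros(C, dtype=np.int8)
            label[ci] = 1
            if rng.random() < grammar.embed_prob:
                inst = grammar.instance(rng)
                center = (L - len(inst)) // 2
                jitter = grammar.position_jitter
                offset = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
                pos = int(np.clip(center + offset, 0, L - len(inst)))
                seq = _embed(seq, inst, pos)
                add(seq, label, grammar.class_name, True, inst.id, pos)
            else:
                add(seq, label, grammar.class_name, False, "", None)
    for _ in range(spec.resolved_n_negative()):
        add(
            _random_sequence(rng, L, spec.gc), np.zeros(C, dtype=np.int8),
            "negative", False, "", None,
        )

    # shuffle so classes are interleaved, then assign provenance round-robin
    order = rng.permutation(len(sequences))
    sequences = [sequences[i] for i in order]
    labels = [labels[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order]).reset_index(drop=True)
    truth["index"] = np.arange(len(truth))

    counters = dict.fromkeys(spec.fake_chroms, 0)
    provenance = []
    for i in range(len(sequences)):
        chrom = spec.fake_chroms[i % len(spec.fake_chroms)]
        k = counters[chrom]
        counters[chrom] += 1
        provenance.append(GenomicRegion(chrom, k * L, (k + 1) * L))
    truth["chrom"] = [r.chrom for r in provenance]

    dataset = LabeledDataset(
        sequences=sequences,
        labels=np.stack(labels),
        class_names=spec.class_names,
        provenance=provenance,
        window_length=L,
    )
    return dataset, truth


def generate_background_pool(spec: SyntheticSpec, M: int = 24, seed: int = 0):
    """M grammar-free background sequences at the spec's GC content.

    No sequence contains any grammar motif's consensus template as an
    exact substring (resampled on collision), mirroring backgrounds
    drawn from closed chromatin.
    """
    from .pattern_effect import BackgroundSet

    rng = np.random.default_rng(seed)
    forbidden = [t for g in spec.grammars for t in g.motif_templates()]
    sequences = []
    while len(sequences) < M:
        seq = _random_sequence(rng, spec.window_length, spec.gc)
        if any(t in seq for t in forbidden):
            continue
        sequences.append(seq)
    return BackgroundSet(sequences=sequences, source="synthetic", seed=seed)


def imbalance_pair(spec: SyntheticSpec, factor: int) -> tuple[SyntheticSpec, SyntheticSpec]:
    """A balanced spec and a copy with the second class inflated ``factor``-fold.

    Shares the seed and everything else, so the two datasets differ
    only in class-2 depth — the controlled comparison for studying how
    class imbalance distorts effect estimates.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n = list(spec.n_per_class)
    n[1] = n[1] * factor
    # freeze the negative count so the pair differs only in class-2 depth
    balanced = replace(spec, n_negative=spec.resolved_n_negative())
    return balanced, replace(balanced, n_per_class=n)


# ---------------------------------------------------------------------------
# fixture export
# ---------------------------------------------------------------------------


def demo_spec(n_per_class: int = 500, seed: int = 0) -> SyntheticSpec:
    """The standard 2-class demo: one motif per class, jittered center embeds."""
    pwm_a = pwm_from_consensus("motifA", "TGACTCAG")
    pwm_b = pwm_from_consensus("motifB", "CACGTGAC")
    return SyntheticSpec(
        grammars=[
            GrammarSpec("class1", [pwm_a]),
            GrammarSpec("class2", [pwm_b]),
        ],
        n_per_class=[n_per_class, n_per_class],
        seed=seed,
    )


def spacing_spec(
    n_per_class: int = 800,
    gap: int = 3,
    alt_gap: int = 8,
    seed: int = 0,
) -> SyntheticSpec:
    """Two classes built from the same motif pair at different gaps.

    Class 1 embeds the pair at ``gap`` bp, class 2 at ``alt_gap`` bp, so
    the only feature separating the classes is motif spacing — the
    setting a spacing scan is meant to recover. The motif cores are the
    canonical Sox2 (TTGT) and Oct4 (ATGCAA) strings.
    """
    pwm_a = pwm_from_consensus("sox2_core", "TTGT")
    pwm_b = pwm_from_consensus("oct4_core", "ATGCAA")
    return SyntheticSpec(
        grammars=[
            GrammarSpec("paired_near", [pwm_a, pwm_b], spacing=(0, 1, gap)),
            GrammarSpec("paired_far", [pwm_a, pwm_b], spacing=(0, 1, alt_gap)),
        ],
        n_per_class=[n_per_class, n_per_class],
        seed=seed,
    )


def write_fixture(spec: SyntheticSpec, out_dir) -> dict[str, str]:
    """Write a generated dataset in both ingestion formats.

    Produces sequences.fa + labels.tsv (FASTA mode), genome.fa plus one
    BED per class (BED mode; the fake genome is the provenance windows
    laid end to end per chromosome), a grammar-free backgrounds.fa, the
    motif panel in HOCOMOCO format, and the ground-truth table.
    """
    from pathlib import Path

    from .genomic_io import write_fasta, write_label_table
    from .motifs import write_hocomoco

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, truth = generate_dataset(spec)
    write_fasta(out / "sequences.fa", {f"seq_{i}": s for i, s in enumerate(dataset.sequences)})
    write_label_table(out / "labels.tsv", dataset.class_names, dataset.labels)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    # fake genome: windows are contiguous per chromosome by construction
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for seq, region in zip(dataset.sequences, dataset.provenance):
        by_chrom.setdefault(region.chrom, []).append((region.start, seq))
    genome = {
        chrom: "".join(s for _, s in sorted(parts))
        for chrom, parts in by_chrom.items()
    }
    write_fasta(out / "genome.fa", genome)
    paths = {
        "sequences": str(out / "sequences.fa"),
        "labels": str(out / "labels.tsv"),
        "genome": str(out / "genome.fa"),
        "truth": str(out / "truth.tsv"),
    }
    for ci, cname in enumerate(dataset.class_names):
        bed = out / f"{cname}.bed"
        with open(bed, "w") as fh:
            for li, region in enumerate(dataset.provenance):
                if dataset.labels[li, ci]:
                    fh.write(f"{region.chrom}\t{region.start}\t{region.end}\n")
        paths[f"bed_{cname}"] = str(bed)

    pool = generate_background_pool(spec, M=24, seed=spec.seed + 1)
    pool.to_fasta(out / "backgrounds.fa")
    paths["backgrounds"] = str(out / "backgrounds.fa")

    embedded = [m for g in spec.grammars for m in g.motifs if isinstance(m, PWM)]
    panel = embedded + (spec.decoy_motifs or decoy_panel(embedded, seed=spec.seed + 2))
    write_hocomoco(out / "motif_panel.txt", panel)
    paths["motifs"] = str(out / "motif_panel.txt")
    return paths


# ---------------------------------------------------------------------------
# motif panels
# ---------------------------------------------------------------------------


def pwm_from_consensus(name: str, seq: str, major: float = 0.85) -> PWM:
    """Sharp PWM whose argmax path spells ``seq``; off-bases share 1 - major."""
    minor = (1 - major) / 3
    mat = np.full((len(seq), 4), minor)
    for i, base in enumerate(seq.upper()):
        mat[i, "ACGT".index(base)] = major
    return PWM(name=name, matrix=mat, source="raw")


def random_pwm(name: str, length: int, rng: np.random.Generator,
               major: float = 0.85) -> PWM:
    seq = "".join(_BASES[rng.integers(0, 4, size=length)])
    return pwm_from_consensus(name, seq, major)


def shuffled_pwm(pwm: PWM, rng: np.random.Generator) -> PWM:
    """Column-shuffled version of a PWM (same composition, scrambled order)."""
    perm = rng.permutation(len(pwm))
    return PWM(name=f"{pwm.name}_shuf", matrix=pwm.matrix[perm], source=pwm.source)


def _max_alignment_identity(a: str, b: str, min_overlap: int = 4) -> int:
    """Best gapless alignment match count between two strings."""
    best = 0
    for off in range(-(len(a) - min_overlap), len(b) - min_overlap + 1):
        matches = sum(
            1
            for i in range(len(a))
            if 0 <= i + off < len(b) and a[i] == b[i + off]
        )
        best = max(best, matches)
    return best


def decoy_panel(
    embedded: list[PWM],
    n_random: int = 18,
    length: int = 8,
    seed: int = 0,
    max_identity: int = 4,
) -> list[PWM]:
    """Screen panel: the embedded motifs' shuffles plus random decoys.

    Decoys are true negatives by construction: any candidate whose
    consensus aligns to an embedded-motif consensus with more than
    ``max_identity`` matching positions (over all gapless offsets, on
    either strand — motif detectors for palindromic cores respond to
    both orientations) is resampled, so a "significant decoy" reflects
    a model failure rather than an accidental near-duplicate of the
    real motif. With the defaults and two embedded motifs this yields
    20 panel entries.
    """
    rng = np.random.default_rng(seed)
    targets = [consensus(p).template for p in embedded]

    def dissimilar(cand: PWM) -> bool:
        fwd = consensus(cand).template
        rc = consensus(cand).reverse_complement().template
        return all(
            _max_alignment_identity(c, t) <= max_identity
            for t in targets
            for c in (fwd, rc)
        )

    panel: list[PWM] = []
    for p in embedded:
        cand = shuffled_pwm(p, rng)
        while not dissimilar(cand):
            cand = shuffled_pwm(p, rng)
        panel.append(cand)
    for i in range(n_random):
        cand = random_pwm(f"decoy{i}", length, rng)
        while not dissimilar(cand):
            cand = random_pwm(f"decoy{i}", length, rng)
        panel.append(cand)
    return panel
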