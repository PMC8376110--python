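"""Position weight matrices and insertable sequence patterns.

Motif databases come in two plain-text dialects here: the HOCOMOCO
position count/frequency format (``>name`` header, then one row of four
numbers per motif position) and the HOMER ``.motif`` format
(``>consensus<TAB>name<TAB>log-odds-threshold`` header, then probability
rows). Both are normalized to per-position base probabilities over
A,C,G,T.

A :class:`Pattern` is the concrete nucleotide template that gets
substituted into background sequences: a motif consensus, a PWM-sampled
site, or a motif pair separated by ``*`` wildcards that preserve the
background nucleotide (so a spacing scan measures geometry, not spacer
content).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT*", "TGCA*")


@dataclass(frozen=True)
class PWM:
    """A motif as an L x 4 matrix of per-position base probabilities."""

    name: str
    matrix: np.ndarray
    source: str = "raw"

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", mat)
        if mat.ndim != 2 or mat.shape[1] != 4 or mat.shape[0] < 1:
            raise ValueError(f"PWM {self.name}: matrix must be L x 4 with L >= 1")
        if (mat < 0).any():
            raise ValueError(f"PWM {self.name}: negative entries")
        if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name}: rows must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class Pattern:
    """An insertable nucleotide template over {A,C,G,T,*}.

    ``*`` positions leave the background nucleotide unchanged. ``parts``
    records provenance as (motif name, offset) pairs.
    """

    id: str
    template: str
    parts: tuple[tuple[str, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.template:
            raise ValueError(f"pattern {self.id}: empty template")
        bad = set(self.template) - set("ACGT*")
        if bad:
            raise ValueError(f"pattern {self.id}: invalid characters {sorted(bad)}")
        if set(self.template) == {"*"}:
            raise ValueError(f"pattern {self.id}: template is all wildcards")
        object.__setattr__(self, "parts", tuple(self.parts))

    def __len__(self) -> int:
        return len(self.template)

    def reverse_complement(self) -> "Pattern":
        rc = self.template.translate(_COMPLEMENT)[::-1]
        return Pattern(id=f"{self.id}_rc", template=rc, parts=self.parts)


def _parse_matrix_rows(rows: list[list[float]], name: str, source: str) -> PWM:
    mat = np.asarray(rows, dtype=float)
    if mat.size == 0:
        raise ValueError(f"motif {name}: empty record")
    if (mat < 0).any():
        raise ValueError(f"motif {name}: negative value")
    totals = mat.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError(f"motif {name}: all-zero row")
    return PWM(name=name, matrix=mat / totals, source=source)


def _split_row(line: str, name: str) -> list[float]:
    vals = line.split()
    if len(vals) != 4:
        raise ValueError(f"motif {name}: row with {len(vals)} values, expected 4")
    return [float(v) for v in vals]


def parse_hocomoco(path) -> list[PWM]:
    """Parse a HOCOMOCO plain-text PCM/PWM file into probability PWMs.

    Count matrices and frequency matrices are both accepted; each row is
    divided by its total, so the distinction is immaterial.
    """
    pwms: list[PWM] = []
    name, rows = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    pwms.append(_parse_matrix_rows(rows, name, "hocomoco"))
                name, rows = line[1:].split()[0], []
            else:
                if name is None:
                    raise ValueError(f"{path}: matrix row before any '>' header")
                rows.append(_split_row(line, name))
    if name is not None:
        pwms.append(_parse_matrix_rows(rows, name, "hocomoco"))
    return pwms


def write_hocomoco(path, pwms: list[PWM]) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for row in pwm.matrix:
                fh.write("\t".join(f"{v:.9f}" for v in row) + "\n")


def parse_homer(path) -> list[PWM]:
    """Parse a HOMER ``.motif`` file into probability PWMs.

    Header lines are ``>consensus<TAB>name<TAB>log-odds-threshold``;
    rows that drift slightly from summing to 1 are renormalized.
    """
    pwms: list[PWM] = []
    name, rows = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if name is not None:
                    pwms.append(_parse_matrix_rows(rows, name, "homer"))
                fields = line[1:].split("\t")
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}: HOMER header needs consensus, name and threshold: {line!r}"
                    )
                name, rows = fields[1], []
            else:
                if name is None:
                    raise ValueError(f"{path}: matrix row before any '>' header")
                rows.append(_split_row(line, name))
    if name is not None:
        pwms.append(_parse_matrix_rows(rows, name, "homer"))
    return pwms


def write_homer(path, pwms: list[PWM], threshold: float = 0.0) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            cons = consensus(pwm).template
            fh.write(f">{cons}\t{pwm.name}\t{threshold}\n")
            for row in pwm.matrix:
                fh.write("\t".join(f"{v:.9f}" for v in row) + "\n")


def consensus(pwm: PWM) -> Pattern:
    """Reduce a PWM to its argmax consensus pattern.

    Ties are broken by fixed base order A < C < G < T, so the reduction
    is deterministic.
    """
    idx = pwm.matrix.argmax(axis=1)  # np.argmax takes the first max: A<C<G<T
    template = "".join(_BASES[i] for i in idx)
    return Pattern(id=pwm.name, template=template, parts=((pwm.name, 0),))


def sample_site(pwm: PWM, seed: int) -> Pattern:
    """Draw one concrete binding site from a PWM, position-independently."""
    rng = np.random.default_rng(seed)
    template = "".join(
        _BASES[rng.choice(4, p=row / row.sum())] for row in pwm.matrix
    )
    return Pattern(id=f"{pwm.name}_sampled", template=template, parts=((pwm.name, 0),))


def paired_pattern(a: Pattern, b: Pattern, spacing: int) -> Pattern:
    """Concatenate two patterns with ``spacing`` background-preserving wildcards.

    Negative spacing (overlapping motifs) is not supported.
    """
    if spacing < 0:
        raise ValueError("spacing must be >= 0; overlapping motifs are not supported")
    template = a.template + "*" * spacing + b.template
    parts = tuple((n, off) for n, off in a.parts) + tuple(
        (n, off + len(a) + spacing) for n, off in b.parts
    )
    return Pattern(id=f"{a.id}+{spacing}+{b.id}", template=template, parts=parts)


def read_patterns(path) -> list[Pattern]:
    """Read a plain-text pattern list: one ``id<TAB>template`` per line."""
    patterns = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 'id<TAB>template'")
            patterns.append(Pattern(id=fields[0], template=fields[1].upper()))
    return patterns
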