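import numpy as np
import pytest

from ousiometrics.frameworks import ScoreMatrix
from ousiometrics.lexicon import SyntheticLexiconSpec, generate_synthetic_lexicon


@pytest.fixture(scope="session")
def synth20k():
    """A ~20k-term synthetic centered lexicon with the reference
    correlation structure (r_VaAr=-0.27, r_ArDm=0.30, r_VaDm=0.49)."""
    return generate_synthetic_lexicon(SyntheticLexiconSpec(n_terms=20_000, seed=7))


@pytest.fixture(scope="session")
def vad_scores(synth20k):
    return ScoreMatrix.from_lexicon(synth20k)


@pytest.fixture(scope="session")
def demeaned_scores(synth20k):
    """Score matrix with exactly zero column means, so that SVD
    decorrelation holds for Pearson correlations to machine precision."""
    values = synth20k.scores.to_numpy(dtype=float)
    values = values - values.mean(axis=0)
    return ScoreMatrix(
        terms=list(synth20k.scores.index),
        values=values,
        dims=("Va", "Ar", "Dm"),
        framework="VAD",
    )


@pytest.fixture
def write_lexicon_tsv(tmp_path):
    """Write rows as a lexicon TSV and return the path."""

    def _write(rows, name="lex.tsv", header=None):
        path = tmp_path / name
        lines = []
        if header:
            lines.append("\t".join(header))
        for term, va, ar, dm in rows:
            lines.append(f"{term}\t{va}\t{ar}\t{dm}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    return _write


def toy_scores(entries, dims=("Pw", "Dg"), framework="PDS"):
    """Build a small ScoreMatrix from {term: (coords...)}."""
    terms = list(entries)
    values = np.array([entries[t] for t in terms], dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    return ScoreMatrix(terms=terms, values=values, dims=dims, framework=framework)
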