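"""Lexicon-derived feature space for phoneme-level decoding.

This module builds everything that is known about a phoneme stream *before*
looking at any recording: the binary phonetic feature code, word-internal
cohort statistics (continuation probability, surprisal, cohort entropy,
sequence frequency), boundary and positional covariates, and the lagged
design matrices used for phoneme-history decoding.

Conventions
-----------
* Binary features are coded ±1; continuous features are z-scored within the
  annotated stream.
* Cohorts restart at every word boundary: the prefix used for surprisal and
  entropy is the word-internal phoneme sequence heard so far.
* Surprisal is ``-log2`` of the continuation probability (bits), matching the
  bits reported for cohort entropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PHONETIC_FEATURES",
    "BOUNDARY_FEATURES",
    "POSITIONAL_FEATURES",
    "INFO_FEATURES",
    "ANNOTATION_FEATURES",
    "DEFAULT_FEATURE_SCHEME",
    "FeatureTable",
    "build_feature_table",
    "WordEntry",
    "Lexicon",
    "toy_lexicon",
    "PhonemeEvent",
    "cohort_of",
    "continuation_probability",
    "surprisal",
    "cohort_entropy",
    "annotate_stream",
    "lag_features",
    "read_lexicon",
    "write_lexicon",
    "read_annotation",
    "write_annotation",
]

#: The 14 binary phonetic dimensions: voicing, five manner features and
#: eight place features (four vowel places, four consonant places).
PHONETIC_FEATURES = [
    "voicing",
    "fricative",
    "nasal",
    "plosive",
    "approximant",
    "vowel",
    "vowel_central",
    "vowel_low",
    "vowel_mid",
    "vowel_high",
    "coronal",
    "glottal",
    "labial",
    "velar",
]

INFO_FEATURES = ["surprisal", "entropy", "log_seq_freq"]

BOUNDARY_FEATURES = [
    "word_onset",
    "word_offset",
    "syllable_onset",
    "syllable_offset",
    "morpheme_onset",
    "morpheme_offset",
    "primary_stress",
    "secondary_stress",
]

POSITIONAL_FEATURES = [
    "phoneme_in_syllable",
    "phoneme_in_word",
    "phoneme_in_sentence",
    "syllable_in_word",
    "syllable_in_sentence",
    "word_in_sentence",
]

#: The 31 modelled feature columns, in canonical order.
ANNOTATION_FEATURES = (
    PHONETIC_FEATURES + INFO_FEATURES + BOUNDARY_FEATURES + POSITIONAL_FEATURES
)

_VOWEL_PLACES = ["vowel_central", "vowel_low", "vowel_mid", "vowel_high"]
_CONS_PLACES = ["coronal", "glottal", "labial", "velar"]


def _c(voicing, manner, place):
    """Consonant row: manner in {fricative, nasal, plosive, approximant}."""
    row = {f: 0 for f in PHONETIC_FEATURES}
    row["voicing"] = voicing
    row[manner] = 1
    row[place] = 1
    return row


def _v(place):
    """Vowel row: voiced, manner 'vowel', place among the vowel heights."""
    row = {f: 0 for f in PHONETIC_FEATURES}
    row["voicing"] = 1
    row["vowel"] = 1
    row[place] = 1
    return row


#: Feature assignments for an ASCII-ish English phoneme inventory.
DEFAULT_FEATURE_SCHEME = {
    # plosives
    "p": _c(0, "plosive", "labial"),
    "b": _c(1, "plosive", "labial"),
    "t": _c(0, "plosive", "coronal"),
    "d": _c(1, "plosive", "coronal"),
    "k": _c(0, "plosive", "velar"),
    "g": _c(1, "plosive", "velar"),
    # fricatives
    "f": _c(0, "fricative", "labial"),
    "v": _c(1, "fricative", "labial"),
    "s": _c(0, "fricative", "coronal"),
    "z": _c(1, "fricative", "coronal"),
    "sh": _c(0, "fricative", "coronal"),
    "zh": _c(1, "fricative", "coronal"),
    "th": _c(0, "fricative", "coronal"),
    "dh": _c(1, "fricative", "coronal"),
    "h": _c(0, "fricative", "glottal"),
    # nasals
    "m": _c(1, "nasal", "labial"),
    "n": _c(1, "nasal", "coronal"),
    "ng": _c(1, "nasal", "velar"),
    # approximants
    "l": _c(1, "approximant", "coronal"),
    "r": _c(1, "approximant", "coronal"),
    "w": _c(1, "approximant", "labial"),
    "y": _c(1, "approximant", "velar"),
    # vowels
    "iy": _v("vowel_high"),
    "ih": _v("vowel_high"),
    "uw": _v("vowel_high"),
    "uh": _v("vowel_high"),
    "ey": _v("vowel_mid"),
    "eh": _v("vowel_mid"),
    "ow": _v("vowel_mid"),
    "ao": _v("vowel_mid"),
    "ax": _v("vowel_central"),
    "er": _v("vowel_central"),
    "ae": _v("vowel_low"),
    "aa": _v("vowel_low"),
}


class FeatureTable:
    """Mapping phoneme symbol -> 14 binary phonetic feature values.

    Backed by a pandas DataFrame (rows: phonemes, columns: the 14 features,
    values in {0, 1}).  Use :func:`build_feature_table` to construct one with
    the invariants checked.
    """

    def __init__(self, table: pd.DataFrame):
        self.table = table

    @property
    def inventory(self) -> list[str]:
        return list(self.table.index)

    def row(self, phoneme: str) -> np.ndarray:
        if phoneme not in self.table.index:
            raise KeyError(f"uncovered inventory: phoneme {phoneme!r} has no feature row")
        return self.table.loc[phoneme].to_numpy(dtype=float)

    def signed(self) -> pd.DataFrame:
        """The table on the ±1 scale."""
        return self.table * 2 - 1

    def is_vowel(self, phoneme: str) -> bool:
        return bool(self.table.loc[phoneme, "vowel"])


def build_feature_table(inventory, scheme=None) -> FeatureTable:
    """Build the binary phonetic :class:`FeatureTable` for ``inventory``.

    Parameters
    ----------
    inventory : list of str
        Phoneme symbols that must all be covered.
    scheme : mapping, optional
        phoneme -> {feature: 0/1}; defaults to :data:`DEFAULT_FEATURE_SCHEME`.

    Raises
    ------
    ValueError
        If a symbol has no scheme row ("uncovered inventory") or a row
        violates the vowel/consonant place exclusivity.
    """
    scheme = DEFAULT_FEATURE_SCHEME if scheme is None else scheme
    rows = {}
    for ph in inventory:
        if ph not in scheme:
            raise ValueError(f"uncovered inventory: phoneme {ph!r} has no feature row")
        row = dict(scheme[ph])
        missing = set(PHONETIC_FEATURES) - set(row)
        if missing:
            raise ValueError(f"feature row for {ph!r} missing dimensions {sorted(missing)}")
        rows[ph] = [int(bool(row[f])) for f in PHONETIC_FEATURES]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=PHONETIC_FEATURES)
    vowel = table["vowel"] == 1
    if (table.loc[vowel, _CONS_PLACES].to_numpy().sum() > 0) or (
        table.loc[~vowel, _VOWEL_PLACES].to_numpy().sum() > 0
    ):
        raise ValueError("vowel place bits must be zero for consonants and vice versa")
    return FeatureTable(table)


@dataclass(frozen=True)
class WordEntry:
    """One lexicon entry: pronunciation, corpus frequency and toy morphology."""

    phonemes: tuple[str, ...]
    frequency: float
    stress_idx: int = 0  # index of the primary-stressed phoneme
    stress2_idx: int | None = None
    affix_onset_idx: int | None = None  # toy suffix boundary, if any

    def __post_init__(self):
        if len(self.phonemes) == 0:
            raise ValueError("phoneme sequence must be non-empty")
        if self.frequency <= 0:
            raise ValueError("word frequency must be strictly positive")


@dataclass
class Lexicon:
    """Word -> (phoneme sequence, frequency) mapping with toy morphology."""

    entries: dict[str, WordEntry] = field(default_factory=dict)

    def __post_init__(self):
        for e in self.entries.values():
            if e.frequency <= 0:
                raise ValueError("word frequency must be strictly positive")

    def __len__(self):
        return len(self.entries)

    def __contains__(self, word):
        return word in self.entries

    def inventory(self) -> list[str]:
        phones = set()
        for e in self.entries.values():
            phones.update(e.phonemes)
        return sorted(phones)

    def words(self) -> list[str]:
        return list(self.entries)


@dataclass(frozen=True)
class PhonemeEvent:
    """A single phoneme token in a continuous stream.

    ``pos_from_onset`` is 1-based (P1 = first phoneme of the word);
    ``pos_from_offset`` is negative (P-1 = last phoneme).
    """

    label: str
    onset: float
    duration: float
    word_id: int
    word: str
    pos_from_onset: int
    pos_from_offset: int
    sentence_id: int = 0
    word_in_sentence: int = 0
    syllable_in_word: int = 0
    is_syllable_onset: bool = False
    is_syllable_offset: bool = False
    primary_stress: bool = False
    secondary_stress: bool = False
    is_morpheme_onset: bool = False
    is_morpheme_offset: bool = False

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("phoneme duration must be positive")


# ---------------------------------------------------------------------------
# Cohort statistics
# ---------------------------------------------------------------------------

def _cohort(prefix, lexicon: Lexicon) -> dict[str, float]:
    prefix = tuple(prefix)
    out = {}
    for word, entry in lexicon.entries.items():
        if entry.phonemes[: len(prefix)] == prefix:
            out[word] = entry.frequency
    return out


def cohort_of(prefix, lexicon: Lexicon) -> dict[str, float]:
    """Words whose pronunciation begins with ``prefix``, with frequencies.

    An empty cohort is returned as an empty dict (not an error).
    """
    if len(tuple(prefix)) == 0:
        raise ValueError("prefix must be non-empty")
    return _cohort(prefix, lexicon)


def continuation_probability(prefix, next_phoneme, lexicon: Lexicon) -> float:
    """P(next_phoneme | cohort of prefix), frequency weighted.

    The probability of each continuation p is the summed frequency of cohort
    members whose next phoneme is p, over the total cohort frequency, so the
    probabilities over attested continuations sum to 1.  ``prefix`` may be
    empty, in which case the cohort is the whole lexicon (word onset).
    """
    prefix = tuple(prefix)
    cohort = _cohort(prefix, lexicon)
    if not cohort:
        raise ValueError(f"undefined cohort: no word begins with {' '.join(prefix)!r}")
    k = len(prefix)
    total = sum(cohort.values())
    num = 0.0
    for word, freq in cohort.items():
        seq = lexicon.entries[word].phonemes
        if len(seq) > k and seq[k] == next_phoneme:
            num += freq
    return num / total


def surprisal(prefix, phoneme, lexicon: Lexicon) -> float:
    """Phoneme surprisal in bits: ``-log2 P(phoneme | cohort(prefix))``."""
    p = continuation_probability(prefix, phoneme, lexicon)
    if p <= 0:
        raise ValueError(
            f"zero-probability continuation: {phoneme!r} after {' '.join(prefix)!r}"
        )
    return -math.log2(p)


def cohort_entropy(prefix, lexicon: Lexicon) -> float:
    """Shannon entropy (bits) over the cohort's words, frequency weighted."""
    cohort = _cohort(tuple(prefix), lexicon)
    if not cohort:
        raise ValueError(
            f"undefined cohort: no word begins with {' '.join(tuple(prefix))!r}"
        )
    total = sum(cohort.values())
    ent = 0.0
    for freq in cohort.values():
        p = freq / total
        ent -= p * math.log2(p)
    return ent


# ---------------------------------------------------------------------------
# Toy lexicon and syllabification
# ---------------------------------------------------------------------------

_TOY_WORDS = [
    # word, phonemes, frequency
    ("cat", "k ae t", 42),
    ("cab", "k ae b", 7),
    ("can", "k ae n", 30),
    ("cap", "k ae p", 9),
    ("car", "k aa r", 33),
    ("cart", "k aa r t", 6),
    ("dog", "d ao g", 35),
    ("dot", "d aa t", 8),
    ("dip", "d ih p", 5),
    ("deep", "d iy p", 12),
    ("day", "d ey", 40),
    ("daze", "d ey z", 3),
    ("pet", "p eh t", 14),
    ("pets", "p eh t s", 6),
    ("pest", "p eh s t", 4),
    ("pin", "p ih n", 11),
    ("pig", "p ih g", 9),
    ("path", "p ae th", 8),
    ("bat", "b ae t", 13),
    ("back", "b ae k", 28),
    ("bag", "b ae g", 12),
    ("barn", "b aa r n", 4),
    ("sea", "s iy", 25),
    ("seat", "s iy t", 10),
    ("seal", "s iy l", 5),
    ("sun", "s ax n", 22),
    ("sung", "s ax ng", 3),
    ("ship", "sh ih p", 10),
    ("shine", "sh aa y n", 6),
    ("zip", "z ih p", 4),
    ("zone", "z ow n", 5),
    ("thin", "th ih n", 6),
    ("this", "dh ih s", 60),
    ("that", "dh ae t", 55),
    ("fish", "f ih sh", 15),
    ("fan", "f ae n", 7),
    ("vat", "v ae t", 2),
    ("van", "v ae n", 8),
    ("man", "m ae n", 45),
    ("men", "m eh n", 30),
    ("mill", "m ih l", 5),
    ("nap", "n ae p", 4),
    ("net", "n eh t", 8),
    ("night", "n aa y t", 25),
    ("lake", "l ey k", 9),
    ("light", "l aa y t", 20),
    ("rat", "r ae t", 7),
    ("rug", "r ax g", 4),
    ("run", "r ax n", 24),
    ("wet", "w eh t", 9),
    ("win", "w ih n", 14),
    ("yes", "y eh s", 32),
    ("hat", "h ae t", 12),
    ("hot", "h aa t", 16),
    ("gap", "g ae p", 5),
    ("go", "g ow", 48),
    ("goes", "g ow z", 10),
    ("tiger", "t aa y g er", 6),
    ("table", "t ey b ax l", 18),
    ("garden", "g aa r d ax n", 9),
    ("window", "w ih n d ow", 11),
    ("magnet", "m ae g n eh t", 3),
    ("sunset", "s ax n s eh t", 4),
    ("panda", "p ae n d aa", 3),
    ("banana", "b ax n ae n ax", 5),
]


def toy_lexicon() -> Lexicon:
    """A small, fixed English-like lexicon for synthetic streams.

    Stress falls on the first vowel for monosyllables and alternates to the
    second vowel for every third polysyllabic word; words whose pronunciation
    ends in /s/ or /z/ carry a toy suffix boundary before that phoneme.  The
    assignments are deterministic so that annotated streams are reproducible.
    """
    entries = {}
    poly_i = 0
    for word, phones, freq in _TOY_WORDS:
        seq = tuple(phones.split())
        vowel_idx = [i for i, p in enumerate(seq)
                     if DEFAULT_FEATURE_SCHEME[p]["vowel"] == 1]
        stress2 = None
        if len(vowel_idx) >= 2:
            poly_i += 1
            stress = vowel_idx[1] if poly_i % 3 == 0 else vowel_idx[0]
            stress2 = vowel_idx[1] if stress == vowel_idx[0] else vowel_idx[0]
        else:
            stress = vowel_idx[0] if vowel_idx else 0
        affix = len(seq) - 1 if (len(seq) > 2 and seq[-1] in ("s", "z")) else None
        entries[word] = WordEntry(seq, float(freq), stress, stress2, affix)
    return Lexicon(entries)


def syllabify(phonemes, feature_table: FeatureTable) -> list[int]:
    """Assign a 0-based syllable index to each phoneme of a word.

    Simple nucleus rule: each vowel is a nucleus; a consonant joins the
    following nucleus if one exists (onset-maximising), else the preceding
    one.  Vowel-less words form a single syllable.
    """
    is_v = [feature_table.is_vowel(p) for p in phonemes]
    nuclei = [i for i, v in enumerate(is_v) if v]
    if not nuclei:
        return [0] * len(phonemes)
    out = []
    for i in range(len(phonemes)):
        nxt = [k for k, n in enumerate(nuclei) if n >= i]
        out.append(nxt[0] if nxt else len(nuclei) - 1)
    return out


# ---------------------------------------------------------------------------
# Stream annotation
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def annotate_stream(
    events: list[PhonemeEvent],
    lexicon: Lexicon,
    feature_table: FeatureTable,
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Build the 31-column design matrix for a phoneme stream.

    Returns a DataFrame with one row per event: metadata columns (``label``,
    ``onset_s``, ``duration_s``, ``word_id``, ``pos_from_onset``,
    ``pos_from_offset``, raw grouping columns ``raw_surprisal``,
    ``raw_entropy``, ``word_length``) followed by the 31 feature columns of
    :data:`ANNOTATION_FEATURES`.  Binary features are ±1; surprisal, entropy,
    log sequence frequency and the positional counts are z-scored within the
    stream.

    Surprisal and entropy are computed from the word-internal prefix: the
    cohort restarts at every word onset, and the entropy/sequence-frequency
    cohort includes the current phoneme.
    """
    if not events:
        raise ValueError("no events to annotate")
    rows = []
    signed = feature_table.signed()
    for ev in events:
        if ev.word not in lexicon:
            raise ValueError(f"word {ev.word!r} not in lexicon")
        seq = lexicon.entries[ev.word].phonemes
        k = ev.pos_from_onset - 1
        if k >= len(seq) or seq[k] != ev.label:
            raise ValueError(
                f"event {ev.label!r} at position {ev.pos_from_onset} does not match "
                f"lexicon pronunciation of {ev.word!r}"
            )
        prefix = seq[:k]
        surp = surprisal(prefix, ev.label, lexicon)
        ent = cohort_entropy(seq[: k + 1], lexicon)
        seq_freq = sum(_cohort(seq[: k + 1], lexicon).values())
        row = {
            "label": ev.label,
            "onset_s": ev.onset,
            "duration_s": ev.duration,
            "word_id": ev.word_id,
            "word": ev.word,
            "pos_from_onset": ev.pos_from_onset,
            "pos_from_offset": ev.pos_from_offset,
            "word_length": len(seq),
            "raw_surprisal": surp,
            "raw_entropy": ent,
        }
        for f, val in zip(PHONETIC_FEATURES, signed.loc[ev.label]):
            row[f] = float(val)
        row["surprisal"] = surp
        row["entropy"] = ent
        row["log_seq_freq"] = math.log(seq_freq, log_base)
        row["word_onset"] = 1.0 if ev.pos_from_onset == 1 else -1.0
        row["word_offset"] = 1.0 if ev.pos_from_offset == -1 else -1.0
        row["syllable_onset"] = 1.0 if ev.is_syllable_onset else -1.0
        row["syllable_offset"] = 1.0 if ev.is_syllable_offset else -1.0
        row["morpheme_onset"] = 1.0 if (ev.is_morpheme_onset or ev.pos_from_onset == 1) else -1.0
        row["morpheme_offset"] = 1.0 if (ev.is_morpheme_offset or ev.pos_from_offset == -1) else -1.0
        row["primary_stress"] = 1.0 if ev.primary_stress else -1.0
        row["secondary_stress"] = 1.0 if ev.secondary_stress else -1.0
        row["phoneme_in_syllable"] = 0.0  # filled below
        row["phoneme_in_word"] = float(ev.pos_from_onset)
        row["phoneme_in_sentence"] = 0.0  # filled below
        row["syllable_in_word"] = float(ev.syllable_in_word + 1)
        row["syllable_in_sentence"] = 0.0  # filled below
        row["word_in_sentence"] = float(ev.word_in_sentence + 1)
        rows.append(row)
    df = pd.DataFrame(rows)

    # sentence- and syllable-level counters need the stream context
    ph_in_syl, ph_in_sent, syl_in_sent = [], [], []
    syl_count = sent = -1
    syl_pos = 0
    sent_pos = 0
    sent_syl = 0
    prev_key = None
    for ev in events:
        if ev.sentence_id != sent:
            sent = ev.sentence_id
            sent_pos = 0
            sent_syl = 0
        key = (ev.word_id, ev.syllable_in_word)
        if key != prev_key:
            prev_key = key
            syl_pos = 0
            sent_syl += 1
        syl_pos += 1
        sent_pos += 1
        ph_in_syl.append(syl_pos)
        ph_in_sent.append(sent_pos)
        syl_in_sent.append(sent_syl)
    df["phoneme_in_syllable"] = np.asarray(ph_in_syl, dtype=float)
    df["phoneme_in_sentence"] = np.asarray(ph_in_sent, dtype=float)
    df["syllable_in_sentence"] = np.asarray(syl_in_sent, dtype=float)

    for col in INFO_FEATURES + POSITIONAL_FEATURES:
        df[col] = _zscore(df[col].to_numpy(dtype=float))

    feat = df[ANNOTATION_FEATURES]
    if feat.isna().any().any():
        raise ValueError("annotation table contains missing values")
    assert len(ANNOTATION_FEATURES) == 31
    return df


def lag_features(annotation: pd.DataFrame, n_history: int) -> pd.DataFrame:
    """Expand the 14 phonetic columns with ``n_history`` preceding phonemes.

    Lag-k columns are named ``<feature>_lag<k>`` (lag 0 = current phoneme).
    Lags reach across word boundaries; the first ``n_history`` events of the
    stream have their missing lags padded with 0 (the uninformative midpoint
    of the ±1 scale).
    """
    if n_history < 0:
        raise ValueError("n_history must be >= 0")
    base = annotation[PHONETIC_FEATURES].to_numpy(dtype=float)
    cols = {}
    for k in range(n_history + 1):
        lagged = np.zeros_like(base)
        if k == 0:
            lagged[:] = base
        elif k < len(base):
            lagged[k:] = base[:-k]
        for j, f in enumerate(PHONETIC_FEATURES):
            cols[f"{f}_lag{k}"] = lagged[:, j]
    return pd.DataFrame(cols, index=annotation.index)


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def write_lexicon(lexicon: Lexicon, path) -> None:
    rows = [
        {"word": w, "phonemes": " ".join(e.phonemes), "frequency": e.frequency}
        for w, e in lexicon.entries.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_lexicon(path) -> Lexicon:
    df = pd.read_csv(path, sep="\t")
    entries = {}
    for _, r in df.iterrows():
        entries[r["word"]] = WordEntry(tuple(str(r["phonemes"]).split()), float(r["frequency"]))
    return Lexicon(entries)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
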