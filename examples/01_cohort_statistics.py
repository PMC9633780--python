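"""Word-internal cohort statistics from a toy lexicon.

Walks through one word phoneme by phoneme, printing the continuation
probability, surprisal and cohort entropy at each step: as the heard
prefix lengthens, the set of compatible words (the cohort) shrinks,
phonemes become more predictable (surprisal falls) and lexical uncertainty
(entropy) collapses.
"""

from phonoseq.lexicon import (
    cohort_entropy,
    cohort_of,
    continuation_probability,
    surprisal,
    toy_lexicon,
)

lex = toy_lexicon()
word = "cart"
seq = lex.entries[word].phonemes
print(f"word {word!r}, pronounced /{' '.join(seq)}/\n")
print(f"{'prefix':<12}{'next':<6}{'P(p|C)':>8}{'surprisal':>11}{'entropy':>9}{'cohort':>8}")
for k, ph in enumerate(seq):
    prefix = seq[:k]
    p = continuation_probability(prefix, ph, lex)
    s = surprisal(prefix, ph, lex)
    h = cohort_entropy(seq[: k + 1], lex)
    n = len(cohort_of(seq[: k + 1], lex))
    print(f"{' '.join(prefix) or '(onset)':<12}{ph:<6}{p:>8.3f}{s:>11.3f}{h:>9.3f}{n:>8}")

print("\nP(p|C) is frequency weighted over the words still compatible with the")
print("prefix; surprisal = -log2 P is in bits; entropy is over the cohort after")
print("hearing the phoneme. A unique continuation has surprisal 0; a singleton")
print("cohort has entropy 0 (the word is identified).")
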