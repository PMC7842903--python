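"""Corpus-based next-word probability and model evaluation.

The reference model is an interpolated Kneser-Ney n-gram: absolute
discounting at the highest order, continuation counts at the lower orders,
and interpolation (not pure backoff) with a single fixed discount.  For a
context ``h`` of length k−1 the conditional probability of ``w`` is

    p_k(w | h) = max(c(h,w) − d, 0) / c(h,·)
               + d · N1+(h,·) / c(h,·) · p_{k−1}(w | h′)

where at orders below the top the raw counts ``c`` are replaced by
continuation counts N1+(·,g) (number of distinct left contexts), and the
recursion bottoms out in a uniform distribution over the vocabulary plus a
single unknown-word bucket.  Every probability is therefore strictly
positive and every conditional distribution sums to one.

Any object with a ``next_distribution(context)`` method can act as a
probability provider; distributions produced by external models (e.g. a
neural language model) are exchanged through a JSON-lines table keyed by
(sentence_id, position).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "BOS",
    "UNK",
    "tokenize",
    "is_punct",
    "ProbDistribution",
    "EvalReport",
    "KneserNeyModel",
    "train_ngram",
    "next_distribution",
    "evaluate",
    "unigram_class_baseline",
    "DistributionTable",
    "write_arpa",
    "read_arpa",
    "ArpaModel",
]

BOS = "<s>"
UNK = "<unk>"

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


def tokenize(text: str) -> List[str]:
    """Lower-case and split into word and punctuation tokens."""
    return _TOKEN_RE.findall(text.lower())


def is_punct(token: str) -> bool:
    return not re.search(r"\w", token, re.UNICODE)


@dataclass
class ProbDistribution:
    """Probability mass over candidate next words for one context.

    ``tail_mass`` accounts for probability outside the stored ``mass`` map
    (e.g. after top-K truncation); mass + tail always sums to one.
    """

    context_id: object
    mass: Dict[str, float]
    tail_mass: float = 0.0

    def total(self) -> float:
        return sum(self.mass.values()) + self.tail_mass

    def prob(self, form: str, floor: float = 1e-12) -> float:
        """Probability of ``form``; unknown forms fall back to the UNK bucket."""
        p = self.mass.get(form)
        if p is None:
            p = self.mass.get(UNK)
        if p is None:
            p = max(self.tail_mass, floor)
        return max(p, floor)

    def argmax(self) -> str:
        """Most probable form; ties broken by the lexicographically smallest."""
        return min(self.mass, key=lambda w: (-self.mass[w], w))

    def truncate(self, top_k: int) -> "ProbDistribution":
        keep = sorted(self.mass, key=lambda w: (-self.mass[w], w))[:top_k]
        mass = {w: self.mass[w] for w in keep}
        return ProbDistribution(self.context_id, mass,
                                self.tail_mass + (sum(self.mass.values()) - sum(mass.values())))


@dataclass
class EvalReport:
    accuracy: float
    perplexity: float
    n_evaluated: int


class LanguageModelError(ValueError):
    pass


def _count_tables(sentences: Sequence[Sequence[str]], order: int):
    """Raw k-gram counts for k=1..order over BOS-padded sentences.

    Windows ending in BOS are skipped: the model never predicts a sentence
    start, which keeps every conditional distribution normalized over the
    word vocabulary plus UNK.
    """
    counts: List[Dict[tuple, int]] = [dict() for _ in range(order + 1)]  # index by k
    pad = (BOS,) * (order - 1)
    for sent in sentences:
        seq = pad + tuple(sent)
        n = len(seq)
        for k in range(1, order + 1):
            table = counts[k]
            for i in range(n - k + 1):
                gram = seq[i:i + k]
                if gram[-1] == BOS:
                    continue
                table[gram] = table.get(gram, 0) + 1
    return counts


class KneserNeyModel:
    """Interpolated Kneser-Ney n-gram model with a capped vocabulary."""

    def __init__(self, sentences: Sequence[Sequence[str]], order: int,
                 discount: float = 0.75, vocab_cap: int | None = None):
        if not sentences or all(len(s) == 0 for s in sentences):
            raise LanguageModelError("empty training corpus")
        if not (1 <= order <= 7):
            raise LanguageModelError("order must be in 1..7")
        if not (0.0 < discount < 1.0):
            raise LanguageModelError("discount must be in (0,1)")
        self.order = order
        self.discount = discount

        freq: Dict[str, int] = {}
        for sent in sentences:
            for tok in sent:
                freq[tok] = freq.get(tok, 0) + 1
        types = sorted(freq, key=lambda w: (-freq[w], w))
        if vocab_cap is not None:
            types = types[:vocab_cap]
        self.vocabulary: List[str] = sorted(types)
        vocab_set = set(self.vocabulary)
        mapped = [[t if t in vocab_set else UNK for t in sent] for sent in sentences]

        self._counts = _count_tables(mapped, order)
        # Continuation counts for orders 1..order-1.
        self._cont: List[Dict[tuple, int]] = [dict() for _ in range(order)]
        for k in range(1, order):
            cont = self._cont[k]
            for gram in self._counts[k + 1]:
                suffix = gram[1:]
                cont[suffix] = cont.get(suffix, 0) + 1
        # Per-context totals and distinct-continuation counts.
        self._ctx_total: List[Dict[tuple, float]] = [dict() for _ in range(order + 1)]
        self._ctx_distinct: List[Dict[tuple, int]] = [dict() for _ in range(order + 1)]
        self._ctx_words: List[Dict[tuple, list]] = [dict() for _ in range(order + 1)]
        for k in range(1, order + 1):
            source = self._counts[k] if k == order else self._cont[k]
            tot, dis, wrd = self._ctx_total[k], self._ctx_distinct[k], self._ctx_words[k]
            for gram, c in source.items():
                ctx = gram[:-1]
                tot[ctx] = tot.get(ctx, 0) + c
                dis[ctx] = dis.get(ctx, 0) + 1
                wrd.setdefault(ctx, []).append((gram[-1], c))

        self._support = self.vocabulary + ([UNK] if UNK not in vocab_set else [])
        self._index = {w: i for i, w in enumerate(self._support)}

    # -- probability queries -------------------------------------------------

    def _map_context(self, context: Sequence[str]) -> tuple:
        vocab = self._index
        ctx = tuple(t if (t in vocab or t == BOS) else UNK for t in context)
        pad = (BOS,) * max(0, self.order - 1 - len(ctx))
        full = pad + tuple(ctx)
        return full[len(full) - (self.order - 1):] if self.order > 1 else ()

    def _dist_vector(self, ctx: tuple) -> np.ndarray:
        """Full conditional distribution over the support, as an array."""
        d = self.discount
        V = len(self._support)
        p = np.full(V, 1.0 / V)  # uniform base over vocab (+ UNK bucket)
        for k in range(1, self.order + 1):
            sub = ctx[len(ctx) - (k - 1):] if k > 1 else ()
            total = self._ctx_total[k].get(sub)
            if not total:
                continue
            lam = d * self._ctx_distinct[k][sub] / total
            p *= lam
            for w, c in self._ctx_words[k][sub]:
                p[self._index[w]] += max(c - d, 0.0) / total
        return p

    def prob(self, word: str, context: Sequence[str]) -> float:
        ctx = self._map_context(context)
        w = word if word in self._index else UNK
        return float(self._dist_vector(ctx)[self._index[w]])

    def _interp_prob(self, word: str, ctx: tuple) -> float:
        """Interpolated probability at level len(ctx)+1, no BOS padding.

        Used for serialization, where each stored k-gram must carry the
        level-k probability rather than the padded full-order one.
        """
        d = self.discount
        w = word if word in self._index else UNK
        p = 1.0 / len(self._support)
        for k in range(1, len(ctx) + 2):
            sub = ctx[len(ctx) - (k - 1):] if k > 1 else ()
            total = self._ctx_total[k].get(sub)
            if not total:
                continue
            table = self._counts[k] if k == self.order else self._cont[k]
            c = table.get(sub + (w,), 0)
            p = p * (d * self._ctx_distinct[k][sub] / total) + max(c - d, 0.0) / total
        return p

    def next_distribution(self, context: Sequence[str],
                          context_id: object = None,
                          top_k: int | None = None) -> ProbDistribution:
        ctx = self._map_context(context)
        vec = self._dist_vector(ctx)
        dist = ProbDistribution(context_id, {w: float(vec[i]) for i, w in enumerate(self._support)})
        if top_k is not None:
            dist = dist.truncate(top_k)
        return dist


def train_ngram(corpus: Sequence[Sequence[str]], order: int,
                discount: float = 0.75, vocab_cap: int | None = None) -> KneserNeyModel:
    """Train an interpolated Kneser-Ney model; see :class:`KneserNeyModel`."""
    return KneserNeyModel(corpus, order, discount, vocab_cap)


def next_distribution(provider, context: Sequence[str], **kw) -> ProbDistribution:
    return provider.next_distribution(context, **kw)


def evaluate(provider, test_corpus: Sequence[Sequence[str]]) -> EvalReport:
    """Accuracy (argmax hit rate) and perplexity over a tokenized test corpus.

    Sentence-initial tokens and punctuation tokens are not scored.
    """
    if not test_corpus:
        raise LanguageModelError("empty test corpus")
    n = 0
    hits = 0
    log_sum = 0.0
    for sent in test_corpus:
        for i, target in enumerate(sent):
            if i == 0 or is_punct(target):
                continue
            dist = provider.next_distribution(sent[:i])
            p = dist.prob(target)
            log_sum += math.log(p)
            hits += int(dist.argmax() == target)
            n += 1
    if n == 0:
        raise LanguageModelError("nothing to evaluate")
    return EvalReport(accuracy=hits / n, perplexity=math.exp(-log_sum / n), n_evaluated=n)


def unigram_class_baseline(tagged_corpus: Iterable[tuple]) -> Dict[str, float]:
    """Word-class probabilities proportional to token counts.

    ``tagged_corpus`` yields (form, analyses) pairs.  A token ambiguous
    between several classes contributes one count to each distinct class
    (permissive counting), so with ambiguity the masses may sum to more
    than one; with unambiguous tags they sum to exactly one.
    """
    counts: Dict[str, int] = {}
    n = 0
    for _form, analyses in tagged_corpus:
        n += 1
        for wc in {a.word_class for a in analyses}:
            counts[wc] = counts.get(wc, 0) + 1
    if n == 0:
        raise LanguageModelError("empty tagged corpus")
    return {wc: c / n for wc, c in sorted(counts.items())}


class DistributionTable:
    """Next-word distributions keyed by (sentence_id, position).

    The exchange format for external providers: JSON-lines, one record per
    stimulus position, carrying the top-K mass map and the tail mass.
    """

    def __init__(self):
        self._table: Dict[Tuple[object, int], ProbDistribution] = {}

    def put(self, sentence_id, position: int, dist: ProbDistribution) -> None:
        self._table[(sentence_id, position)] = dist

    def get(self, sentence_id, position: int) -> ProbDistribution:
        return self._table[(sentence_id, position)]

    def __contains__(self, key) -> bool:
        return tuple(key) in self._table

    def items(self):
        return sorted(self._table.items())

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for (sid, pos), dist in self.items():
                rec = {"sentence_id": sid, "position": pos,
                       "mass": {w: dist.mass[w] for w in sorted(dist.mass)},
                       "tail_mass": dist.tail_mass}
                fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "DistributionTable":
        table = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                rec = json.loads(line)
                key = (rec["sentence_id"], rec["position"])
                table.put(*key, ProbDistribution(key, dict(rec["mass"]),
                                                 float(rec.get("tail_mass", 0.0))))
        return table


# -- ARPA serialization ------------------------------------------------------
#
# Interpolated KN admits an exact backoff representation: store the
# interpolated probability for every seen n-gram and the interpolation
# weight lambda(h) as the backoff weight of context h.  For unseen (h, w),
# lambda(h) * p(w | h') equals the interpolated probability, so the backoff
# model reproduces the interpolated one exactly.


def _all_grams(model: KneserNeyModel):
    grams: List[Dict[tuple, float]] = [dict() for _ in range(model.order + 1)]
    for k in range(1, model.order + 1):
        source = model._counts[k] if k == model.order else model._cont[k]
        for gram in source:
            grams[k][gram] = model._interp_prob(gram[-1], gram[:-1])
    return grams


def write_arpa(model: KneserNeyModel, path: str | Path) -> None:
    grams = _all_grams(model)
    d = model.discount
    bows: List[Dict[tuple, float]] = [dict() for _ in range(model.order)]
    for k in range(1, model.order):
        for ctx in model._ctx_total[k + 1]:
            total = model._ctx_total[k + 1][ctx]
            bows[k][ctx] = d * model._ctx_distinct[k + 1][ctx] / total
    # BOS-bearing contexts (e.g. the all-BOS context) never occur as
    # continuations, so they get dummy probability lines carrying only
    # their backoff weight; UNK keeps the unknown bucket in the file.
    for k in range(1, model.order):
        for ctx in bows[k]:
            if ctx not in grams[k]:
                grams[k][ctx] = 1e-99
    if (UNK,) not in grams[1]:
        grams[1][(UNK,)] = model._interp_prob(UNK, ())
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\\data\\\n")
        for k in range(1, model.order + 1):
            fh.write(f"ngram {k}={len(grams[k])}\n")
        for k in range(1, model.order + 1):
            fh.write(f"\n\\{k}-grams:\n")
            for gram in sorted(grams[k]):
                logp = math.log10(grams[k][gram])
                line = f"{logp!r}\t{' '.join(gram)}"
                if k < model.order and gram in bows[k]:
                    line += f"\t{math.log10(bows[k][gram])!r}"
                fh.write(line + "\n")
        fh.write("\n\\end\\\n")


class ArpaModel:
    """Backoff n-gram model loaded from an ARPA file."""

    def __init__(self, probs: List[Dict[tuple, float]], bows: List[Dict[tuple, float]]):
        self.order = len(probs) - 1
        self._probs = probs
        self._bows = bows
        support = {g[0] for g in probs[1] if g[0] != BOS}
        self.support = sorted(support)

    def prob(self, word: str, context: Sequence[str]) -> float:
        ctx = tuple(context)[max(0, len(context) - (self.order - 1)):]
        pad = (BOS,) * max(0, self.order - 1 - len(ctx))
        ctx = pad + ctx
        ctx = tuple(t if (t,) in self._probs[1] else UNK for t in ctx)
        w = word if (word,) in self._probs[1] else UNK
        return self._score(w, ctx)

    def _score(self, w: str, ctx: tuple) -> float:
        gram = ctx + (w,)
        k = len(gram)
        if k <= self.order and gram in self._probs[k]:
            return self._probs[k][gram]
        if not ctx:
            return self._probs[1].get((w,), 1e-99)
        bow = self._bows[len(ctx)].get(ctx, 1.0) if len(ctx) < len(self._bows) else 1.0
        return bow * self._score(w, ctx[1:])

    def next_distribution(self, context: Sequence[str],
                          context_id: object = None) -> ProbDistribution:
        mass = {w: self.prob(w, context) for w in self.support}
        return ProbDistribution(context_id, mass)


def read_arpa(path: str | Path) -> ArpaModel:
    probs: List[Dict[tuple, float]] = [dict()]
    bows: List[Dict[tuple, float]] = [dict()]
    order = 0
    with open(path, encoding="utf-8") as fh:
        section = 0
        for line in fh:
            line = line.strip()
            if not line or line.startswith("\\data\\") or line == "\\end\\":
                continue
            m = re.match(r"\\(\d+)-grams:", line)
            if m:
                section = int(m.group(1))
                while len(probs) <= section:
                    probs.append(dict())
                    bows.append(dict())
                order = max(order, section)
                continue
            if line.startswith("ngram"):
                continue
            if section:
                parts = line.split("\t")
                logp = float(parts[0])
                gram = tuple(parts[1].split(" "))
                probs[section][gram] = 10.0 ** logp
                if len(parts) > 2:
                    bows[section][gram] = 10.0 ** float(parts[2])
    return ArpaModel(probs, bows)
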