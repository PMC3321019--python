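"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

from pinminer.tagger import MAX_EXTENSIONS, softened, tokenize


def brute_force_tag(sentence, dictionary) -> list[tuple[int, int, str]]:
    """Leftmost-longest protein tagging by exhaustive entry enumeration.

    Enumerates every dictionary entry at every token position (no index,
    no trie), honoring the case rules (single-token entries exact case,
    multi-token case-insensitive), then resolves left-to-right picking
    the longest base match and extending through modifier/head tokens.
    Returns (start, end, matched_entry) triples on the preprocessed text.
    """

    work = softened(sentence.preprocessed)
    tokens = tokenize(work)
    n = len(tokens)
    entries = sorted(dictionary.entries)

    def best_match(i):
        best = None  # (n_tokens, entry)
        for entry in entries:
            etoks = softened(entry).split()
            length = len(etoks)
            if not etoks or i + length > n:
                continue
            window = [tokens[i + k][0] for k in range(length)]
            if length == 1:
                ok = window[0] == etoks[0]
            else:
                ok = [w.casefold() for w in window] == \
                     [e.casefold() for e in etoks]
            if ok and (best is None or length >= best[0]):
                best = (length, entry)
        return best

    mentions = []
    i = 0
    while i < n:
        best = best_match(i)
        if best is None:
            i += 1
            continue
        length, entry = best
        last = i + length - 1
        ext = 0
        while ext < MAX_EXTENSIONS and last + 1 < n:
            nxt = tokens[last + 1][0].casefold()
            if nxt in dictionary.general_terms or nxt in dictionary.head_extensions:
                last += 1
                ext += 1
            else:
                break
        mentions.append((tokens[i][1], tokens[last][2], entry))
        i = last + 1
    return mentions
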