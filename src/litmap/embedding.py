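"""Abstract embeddings under a mean-pooling contract.

The reference pipeline encodes each abstract with a biomedical transformer
(768 hidden units, inputs truncated to 512 tokens) and pools the last hidden
states by taking their arithmetic mean across token positions.  That encoder
is expensive and optional here; the contract is what matters downstream, so
any object implementing :class:`Encoder` can stand behind
:func:`embed_abstracts`:

* :class:`HashingEncoder` — a deterministic, dependency-free encoder that
  maps whitespace tokens to signed coordinates by hashing and mean-pools
  them.  It preserves bag-of-words similarity (documents drawn from disjoint
  vocabularies get near-orthogonal vectors), which is all the synthetic
  pipeline needs, and is the default for tests.
* :class:`TransformerEncoder` — a thin adapter over a Hugging Face model id,
  imported lazily so the heavy stack is only needed when actually used.
"""

from __future__ import annotations

import hashlib
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np

from .records import Corpus

DEFAULT_DIM = 768
DEFAULT_MAX_TOKENS = 512

#: reference encoder id used by the original analysis; requires the optional
#: transformers/torch stack
REFERENCE_ENCODER_ID = "microsoft/BiomedNLP-PubMedBERT-base-uncased-abstract-fulltext"


@runtime_checkable
class Encoder(Protocol):
    """Anything that maps a batch of texts to fixed-width vectors."""

    dim: int

    def encode(self, texts: Sequence[str]) -> np.ndarray:  # (n, dim)
        ...


def mean_pool(
    hidden_states: np.ndarray,
    attention_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Pool per-token hidden states ``(n, tokens, dim)`` to ``(n, dim)``.

    With an attention mask the mean runs over real token positions only
    (mask-aware pooling, the default downstream); without one it is the
    plain mean over all positions.
    """
    hidden = np.asarray(hidden_states, dtype=np.float64)
    if hidden.ndim != 3:
        raise ValueError("hidden_states must have shape (n, tokens, dim)")
    if attention_mask is None:
        return hidden.mean(axis=1)
    mask = np.asarray(attention_mask, dtype=np.float64)[:, :, None]
    denom = np.clip(mask.sum(axis=1), 1.0, None)
    return (hidden * mask).sum(axis=1) / denom


def embed_abstracts(
    corpus: Corpus, encoder: Encoder, batch_size: int = 32
) -> np.ndarray:
    """Encode every abstract; returns an ``(n, encoder.dim)`` matrix.

    Results are independent of ``batch_size`` (up to floating accumulation)
    and deterministic given the encoder and inputs.  An encoder failure is
    re-raised naming the offending record.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    rows: list[np.ndarray] = []
    records = corpus.records
    for start in range(0, len(records), batch_size):
        batch = records[start : start + batch_size]
        try:
            encoded = np.asarray(
                encoder.encode([r.abstract for r in batch]), dtype=np.float64
            )
        except Exception as exc:
            # retry one-by-one so the error names the offending record
            culprit = batch[0].pmid
            for record in batch:
                try:
                    encoder.encode([record.abstract])
                except Exception:
                    culprit = record.pmid
                    break
            raise RuntimeError(
                f"encoder failed on record pmid={culprit}"
            ) from exc
        if encoded.shape != (len(batch), encoder.dim):
            raise ValueError(
                f"encoder returned shape {encoded.shape}, expected "
                f"({len(batch)}, {encoder.dim})"
            )
        rows.append(encoded)
    if not rows:
        return np.empty((0, encoder.dim), dtype=np.float64)
    matrix = np.vstack(rows)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("embedding matrix contains non-finite entries")
    return matrix


class HashingEncoder:
    """Deterministic hashed bag-of-words encoder with mean pooling.

    Each whitespace token (text lowercased, truncated to ``max_tokens``) is
    hashed to a coordinate index and a sign; the document vector is the mean
    of its token vectors, mirroring the mean-pooling contract.  Identical
    texts always give identical vectors; the empty text maps to all zeros by
    convention.
    """

    def __init__(
        self,
        dim: int = DEFAULT_DIM,
        max_tokens: int = DEFAULT_MAX_TOKENS,
        seed: int = 0,
    ):
        self.dim = dim
        self.max_tokens = max_tokens
        self.seed = seed
        self._salt = f"hash-encoder-{seed}".encode()

    def _token_feature(self, token: str) -> tuple[int, float]:
        digest = hashlib.blake2b(
            token.encode("utf-8"), key=self._salt, digest_size=8
        ).digest()
        value = int.from_bytes(digest, "big")
        index = value % self.dim
        sign = 1.0 if (value >> 63) & 1 else -1.0
        return index, sign

    def encode_one(self, text: str) -> np.ndarray:
        vector = np.zeros(self.dim, dtype=np.float64)
        tokens = text.lower().split()[: self.max_tokens]
        if not tokens:
            return vector
        for token in tokens:
            index, sign = self._token_feature(token)
            vector[index] += sign
        return vector / len(tokens)

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        if not texts:
            return np.empty((0, self.dim), dtype=np.float64)
        return np.vstack([self.encode_one(text) for text in texts])


def hash_encoder(seed: int = 0, dim: int = DEFAULT_DIM) -> HashingEncoder:
    """Convenience constructor for the deterministic test encoder."""
    return HashingEncoder(dim=dim, seed=seed)


class TransformerEncoder:
    """Adapter exposing a Hugging Face masked-LM encoder under the contract.

    Tokenizes with padding and truncation to ``max_tokens`` and mean-pools
    the last hidden states (mask-aware by default; set ``mask_aware=False``
    for the plain mean over all positions including padding).  Imports the
    transformers/torch stack lazily: constructing this class raises
    ``ImportError`` when they are not installed.
    """

    def __init__(
        self,
        model_id: str = REFERENCE_ENCODER_ID,
        max_tokens: int = DEFAULT_MAX_TOKENS,
        device: str = "cpu",
        mask_aware: bool = True,
    ):  # pragma: no cover - requires optional heavy dependencies
        import torch  # noqa: F401
        from transformers import AutoModel, AutoTokenizer

        self._torch = torch
        self.tokenizer = AutoTokenizer.from_pretrained(model_id)
        self.model = AutoModel.from_pretrained(model_id).to(device).eval()
        self.dim = int(self.model.config.hidden_size)
        self.max_tokens = max_tokens
        self.device = device
        self.mask_aware = mask_aware

    def encode(self, texts: Sequence[str]) -> np.ndarray:  # pragma: no cover
        torch = self._torch
        batch = self.tokenizer(
            list(texts),
            padding=True,
            truncation=True,
            max_length=self.max_tokens,
            return_tensors="pt",
        ).to(self.device)
        with torch.no_grad():
            hidden = self.model(**batch).last_hidden_state.cpu().numpy()
        mask = (
            batch["attention_mask"].cpu().numpy() if self.mask_aware else None
        )
        return mean_pool(hidden, mask)


__all__ = [
    "DEFAULT_DIM",
    "DEFAULT_MAX_TOKENS",
    "Encoder",
    "HashingEncoder",
    "REFERENCE_ENCODER_ID",
    "TransformerEncoder",
    "embed_abstracts",
    "hash_encoder",
    "mean_pool",
]
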