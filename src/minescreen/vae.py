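"""MSA-conditioned variational autoencoder for homolog generation.

Both encoder and decoder are fully connected networks with ReLU hidden
layers; the decoder ends in a position-wise softmax over the 21-letter
alphabet (20 amino acids + gap).  The training objective is a *weighted*
evidence lower bound,

    Loss = 0.01 * KL + BCE,

where KL is the mean (over latent dimensions) Kullback-Leibler divergence
between the diagonal-Gaussian posterior q(z|x) and the standard-normal
prior, and BCE is the mean (over the flattened one-hot length L) elementwise
binary cross entropy between the input one-hot y and the decoder output ŷ.
Because KL is normalized by the latent dimensionality D while BCE is
normalized by L, the un-weighted objective implicitly scales the KL term by
L/D relative to the reconstruction term; the 0.01 factor pulls that
implicit weight from L/D (244 at L=3906, D=16) down to 0.01*L/D (2.44),
which is what keeps the decoder from collapsing onto a single consensus
sequence.

The network is implemented directly on NumPy arrays with hand-written
backpropagation and an Adam optimizer (β=(0.9, 0.999), ε=1e-8, no weight
decay), so a trained checkpoint is a plain dict of arrays loadable without
any deep-learning framework.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from .msa import ALPHABET, MsaDataset, one_hot_encode

EPS_CLAMP = 1e-7


@dataclass(frozen=True)
class VaeConfig:
    input_width: int
    alphabet_size: int = 21
    hidden_sizes: tuple[int, ...] = (128, 128)
    latent_dim: int = 16
    kl_weight: float = 0.01
    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.kl_weight <= 0:
            raise ValueError("kl_weight must be > 0")

    @property
    def flat_length(self) -> int:
        """L: length of a one-hot encoded, flattened sequence."""
        return self.input_width * self.alphabet_size


def count_parameters(config: VaeConfig) -> int:
    """Exact number of trainable scalars (weights + biases) in encoder and
    decoder.  The encoder has two output heads (μ and σ_log)."""
    L, D = config.flat_length, config.latent_dim
    hidden = list(config.hidden_sizes)
    total = 0
    # encoder trunk + two heads
    prev = L
    for h in hidden:
        total += prev * h + h
        prev = h
    total += 2 * (prev * D + D)
    # decoder trunk + output layer
    prev = D
    for h in hidden:
        total += prev * h + h
        prev = h
    total += prev * L + L
    return total


def kl_divergence(mu: np.ndarray, sigma_log: np.ndarray) -> np.ndarray:
    """Per-sample KL(q(z|x) || N(0, I)) averaged over latent dimensions:
    (1/D) Σ_i -0.5 (1 + σ_log,i - μ_i² - e^{σ_log,i})."""
    mu = np.asarray(mu, dtype=float)
    sigma_log = np.asarray(sigma_log, dtype=float)
    per_dim = -0.5 * (1.0 + sigma_log - mu**2 - np.exp(sigma_log))
    return per_dim.mean(axis=-1)


def binary_cross_entropy(y: np.ndarray, y_hat: np.ndarray) -> np.ndarray:
    """Per-sample elementwise BCE averaged over the flattened length L;
    ŷ is clamped to [1e-7, 1-1e-7] before the logs."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(y_hat, dtype=float), EPS_CLAMP, 1.0 - EPS_CLAMP)
    terms = -(y * np.log(p) + (1.0 - y) * np.log1p(-p))
    return terms.mean(axis=-1)


def elbo_loss(
    y: np.ndarray,
    y_hat: np.ndarray,
    mu: np.ndarray,
    sigma_log: np.ndarray,
    kl_weight: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted ELBO ``total = kl_weight * KL + BCE``.

    ``y``/``y_hat`` carry the flattened one-hot axis last, ``mu``/
    ``sigma_log`` the latent axis last; leading batch axes broadcast.
    Returns (total, KL, BCE), each per sample.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"y shape {y.shape} != y_hat shape {y_hat.shape}")
    kl = kl_divergence(mu, sigma_log)
    bce = binary_cross_entropy(y, y_hat)
    return kl_weight * kl + bce, kl, bce


# ---------------------------------------------------------------------------
# model


def _linear_init(rng: np.random.Generator, fan_in: int, fan_out: int):
    bound = 1.0 / np.sqrt(fan_in)
    W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
    b = rng.uniform(-bound, bound, size=fan_out)
    return W, b


class MsaVae:
    """The MSA-VAE: parameters, training loop, sampling and scoring."""

    def __init__(self, config: VaeConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        L, D = config.flat_length, config.latent_dim
        hidden = list(config.hidden_sizes)
        p: dict[str, np.ndarray] = {}
        prev = L
        for i, h in enumerate(hidden):
            p[f"enc_W{i}"], p[f"enc_b{i}"] = _linear_init(rng, prev, h)
            prev = h
        p["enc_Wmu"], p["enc_bmu"] = _linear_init(rng, prev, D)
        p["enc_Wlv"], p["enc_blv"] = _linear_init(rng, prev, D)
        prev = D
        for i, h in enumerate(hidden):
            p[f"dec_W{i}"], p[f"dec_b{i}"] = _linear_init(rng, prev, h)
            prev = h
        p["dec_Wout"], p["dec_bout"] = _linear_init(rng, prev, L)
        self.params = p
        self._adam_m = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in p.items()}
        self._adam_t = 0
        self.history: dict[str, list[float]] = {"train": [], "validation": []}

    # ---- forward pieces -------------------------------------------------

    def _flatten(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        cfg = self.config
        if x.ndim == 1:
            x = x[None]
        elif x.ndim == 2 and x.shape == (cfg.input_width, cfg.alphabet_size):
            x = x.reshape(1, -1)   # a single (width, alphabet) sample
        elif x.ndim == 3:
            x = x.reshape(x.shape[0], -1)
        if x.ndim != 2 or x.shape[1] != self.config.flat_length:
            raise ValueError(
                f"input width mismatch: got {x.shape[1]} flattened features, "
                f"model expects {self.config.flat_length}"
            )
        return x

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map one-hot input(s) to posterior (μ, σ_log); order preserved."""
        h = self._flatten(x)
        p = self.params
        for i in range(len(self.config.hidden_sizes)):
            h = np.maximum(h @ p[f"enc_W{i}"] + p[f"enc_b{i}"], 0.0)
        return h @ p["enc_Wmu"] + p["enc_bmu"], h @ p["enc_Wlv"] + p["enc_blv"]

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Map latent vectors to (n, width, 21) probability profiles."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        p = self.params
        h = z
        for i in range(len(self.config.hidden_sizes)):
            h = np.maximum(h @ p[f"dec_W{i}"] + p[f"dec_b{i}"], 0.0)
        logits = (h @ p["dec_Wout"] + p["dec_bout"]).reshape(
            z.shape[0], self.config.input_width, self.config.alphabet_size
        )
        logits -= logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=-1, keepdims=True)

    # ---- training -------------------------------------------------------

    def _forward_backward(self, x: np.ndarray, rng: np.random.Generator):
        """One loss + gradient evaluation on a batch; returns
        (total, kl, bce) batch means and the gradient dict."""
        cfg = self.config
        p = self.params
        B = x.shape[0]
        L, D = cfg.flat_length, cfg.latent_dim
        nh = len(cfg.hidden_sizes)

        # encoder forward, caching pre-activations
        h = x
        enc_acts = [h]
        for i in range(nh):
            h = np.maximum(h @ p[f"enc_W{i}"] + p[f"enc_b{i}"], 0.0)
            enc_acts.append(h)
        mu = h @ p["enc_Wmu"] + p["enc_bmu"]
        lv = h @ p["enc_Wlv"] + p["enc_blv"]

        eps = rng.standard_normal(size=mu.shape)
        std = np.exp(0.5 * lv)
        z = mu + std * eps

        dec_acts = [z]
        h = z
        for i in range(nh):
            h = np.maximum(h @ p[f"dec_W{i}"] + p[f"dec_b{i}"], 0.0)
            dec_acts.append(h)
        logits = h @ p["dec_Wout"] + p["dec_bout"]
        lg = logits.reshape(B, cfg.input_width, cfg.alphabet_size)
        lg = lg - lg.max(axis=-1, keepdims=True)
        e = np.exp(lg)
        probs = e / e.sum(axis=-1, keepdims=True)
        y_hat = probs.reshape(B, L)

        total, kl, bce = elbo_loss(x, y_hat, mu, lv, cfg.kl_weight)

        # ---- backward ----
        grads: dict[str, np.ndarray] = {}
        pc = np.clip(y_hat, EPS_CLAMP, 1.0 - EPS_CLAMP)
        # d(mean batch BCE)/d y_hat ; clamp treated as identity
        g_y = -(x / pc - (1.0 - x) / (1.0 - pc)) / (L * B)
        # softmax backward within each 21-channel group
        g3 = g_y.reshape(B, cfg.input_width, cfg.alphabet_size)
        dot = (g3 * probs).sum(axis=-1, keepdims=True)
        g_logits = (probs * (g3 - dot)).reshape(B, L)

        h_last = dec_acts[-1]
        grads["dec_Wout"] = h_last.T @ g_logits
        grads["dec_bout"] = g_logits.sum(axis=0)
        g_h = g_logits @ p["dec_Wout"].T
        for i in range(nh - 1, -1, -1):
            g_h = g_h * (dec_acts[i + 1] > 0)
            grads[f"dec_W{i}"] = dec_acts[i].T @ g_h
            grads[f"dec_b{i}"] = g_h.sum(axis=0)
            g_h = g_h @ p[f"dec_W{i}"].T
        g_z = g_h

        w = cfg.kl_weight
        g_mu = g_z + w * mu / (D * B)
        g_lv = g_z * eps * 0.5 * std + w * 0.5 * (np.exp(lv) - 1.0) / (D * B)

        h_last = enc_acts[-1]
        grads["enc_Wmu"] = h_last.T @ g_mu
        grads["enc_bmu"] = g_mu.sum(axis=0)
        grads["enc_Wlv"] = h_last.T @ g_lv
        grads["enc_blv"] = g_lv.sum(axis=0)
        g_h = g_mu @ p["enc_Wmu"].T + g_lv @ p["enc_Wlv"].T
        for i in range(nh - 1, -1, -1):
            g_h = g_h * (enc_acts[i + 1] > 0)
            grads[f"enc_W{i}"] = enc_acts[i].T @ g_h
            grads[f"enc_b{i}"] = g_h.sum(axis=0)
            g_h = g_h @ p[f"enc_W{i}"].T
        return float(total.mean()), float(kl.mean()), float(bce.mean()), grads

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        b1, b2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        lr = self.config.learning_rate
        for k, g in grads.items():
            m = self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            v = self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def evaluate(self, x: np.ndarray, rng: np.random.Generator) -> float:
        """Mean weighted-ELBO loss over a set (one stochastic pass)."""
        mu, lv = self.encode(x)
        z = mu + np.exp(0.5 * lv) * rng.standard_normal(size=mu.shape)
        y_hat = self.decode(z).reshape(mu.shape[0], -1)
        total, _, _ = elbo_loss(self._flatten(x), y_hat, mu, lv, self.config.kl_weight)
        return float(total.mean())

    def fit(self, dataset: MsaDataset) -> dict[str, list[float]]:
        """Train for exactly ``config.epochs`` epochs (no early stopping);
        batch order is reshuffled each epoch from the run seed."""
        cfg = self.config
        x_train = self._flatten(dataset.subset("train"))
        x_val = self._flatten(dataset.subset("validation"))
        rng = np.random.default_rng(cfg.seed + 1)
        n = x_train.shape[0]
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                batch = x_train[order[start : start + cfg.batch_size]]
                total, _, _, grads = self._forward_backward(batch, rng)
                if not np.isfinite(total):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch + 1}: {total}"
                    )
                self._adam_step(grads)
                losses.append(total)
            self.history["train"].append(float(np.mean(losses)))
            self.history["validation"].append(
                self.evaluate(x_val, rng) if len(x_val) else float("nan")
            )
        return self.history

    # ---- generation and scoring ----------------------------------------

    def sample_and_decode(self, n: int, seed: int = 0) -> np.ndarray:
        """Draw ``n`` latent vectors from N(0, I) and decode to probability
        profiles of shape (n, width, 21)."""
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(size=(n, self.config.latent_dim))
        return self.decode(z)

    def elbo_score(
        self, aligned_sequence: str | np.ndarray, n_passes: int = 200, seed: int = 0
    ) -> float:
        """Mean weighted-ELBO loss of one aligned sequence over
        ``n_passes`` stochastic encode/sample/decode passes (lower means
        the model finds the sequence more plausible)."""
        if isinstance(aligned_sequence, str):
            if len(aligned_sequence) != self.config.input_width:
                raise ValueError(
                    "sequence must be aligned to the model's MSA columns "
                    f"(got length {len(aligned_sequence)}, expected "
                    f"{self.config.input_width}); map it to the MSA first"
                )
            x = one_hot_encode([aligned_sequence])
        else:
            x = np.asarray(aligned_sequence)
        xf = self._flatten(x)
        mu, lv = self.encode(xf)
        rng = np.random.default_rng(seed)
        losses = np.empty(n_passes)
        std = np.exp(0.5 * lv)
        for k in range(n_passes):
            z = mu + std * rng.standard_normal(size=mu.shape)
            y_hat = self.decode(z).reshape(1, -1)
            total, _, _ = elbo_loss(xf, y_hat, mu, lv, self.config.kl_weight)
            losses[k] = total[0]
        return float(losses.mean())

    # ---- checkpointing --------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file archive: config as JSON plus flat named weight
        arrays; loadable with nothing but NumPy."""
        cfg = asdict(self.config)
        cfg["hidden_sizes"] = list(cfg["hidden_sizes"])
        np.savez(path, __config__=json.dumps(cfg), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "MsaVae":
        with np.load(path, allow_pickle=False) as data:
            cfg = json.loads(str(data["__config__"]))
            cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
            model = cls(VaeConfig(**cfg))
            for k in model.params:
                model.params[k] = data[k]
        return model


def decode_to_sequence(profile: np.ndarray, alphabet: str = ALPHABET) -> str:
    """Per-column argmax over the 21 symbols (ties: lowest alphabet index),
    with gap winners stripped — generated sequences are ungapped proteins."""
    idx = np.asarray(profile).argmax(axis=-1)
    return "".join(alphabet[i] for i in idx if alphabet[i] != "-")


def decode_to_aligned(profile: np.ndarray, alphabet: str = ALPHABET) -> str:
    """Argmax decoding keeping gap columns (internal aligned form)."""
    idx = np.asarray(profile).argmax(axis=-1)
    return "".join(alphabet[i] for i in idx)


# ---------------------------------------------------------------------------
# evaluation metrics

_AA = ALPHABET[:20]
_AA_INDEX = {c: i for i, c in enumerate(_AA)}


def aa_frequencies(sequences: list[str]) -> np.ndarray:
    """Amino-acid frequencies over a sequence set; gaps are excluded from
    numerator and denominator.  Returns a length-20 vector summing to 1."""
    if not sequences:
        raise ValueError("empty sequence set")
    counts = np.zeros(20)
    for s in sequences:
        for c in s:
            if c in _AA_INDEX:
                counts[_AA_INDEX[c]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no amino acids in sequence set (all gaps?)")
    return counts / total


def pairwise_aa_frequencies(sequences: list[str]) -> np.ndarray:
    """Joint frequencies of ordered residue pairs (symbol at position i,
    symbol at position j) over all unordered position pairs i<j within each
    sequence, both residues non-gap, pooled over sequences and normalized
    to sum 1.  Returns a (20, 20) matrix."""
    if not sequences:
        raise ValueError("empty sequence set")
    counts = np.zeros((20, 20))
    for s in sequences:
        onehot = np.zeros((len(s), 20))
        for j, c in enumerate(s):
            if c in _AA_INDEX:
                onehot[j, _AA_INDEX[c]] = 1.0
        # sum over i<j of x_i ⊗ x_j via prefix sums
        prefix = np.zeros(20)
        for j in range(len(s)):
            counts += np.outer(prefix, onehot[j])
            prefix += onehot[j]
    total = counts.sum()
    if total == 0:
        raise ValueError("no non-gap position pairs")
    return counts / total


def frequency_correlation(freq_a: np.ndarray, freq_b: np.ndarray) -> float:
    """Pearson correlation between two (flattened) frequency vectors;
    raises on zero variance, where r is undefined."""
    a = np.asarray(freq_a, dtype=float).ravel()
    b = np.asarray(freq_b, dtype=float).ravel()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("frequency correlation undefined: zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def latent_pca(dataset: MsaDataset, model: MsaVae) -> tuple[np.ndarray, np.ndarray]:
    """Encode every sequence, run a centered PCA on the latent means and
    project on the first two principal components.  Returns (n, 2)
    projections and the two explained-variance ratios."""
    mu, _ = model.encode(dataset.encoded)
    if mu.shape[0] < 3:
        raise ValueError("need at least 3 sequences for a latent PCA")
    n_comp = min(2, mu.shape[0], mu.shape[1])
    pca = PCA(n_components=n_comp)
    proj = pca.fit_transform(mu)
    evr = pca.explained_variance_ratio_
    if n_comp < 2:  # rank-deficient trivial case
        proj = np.hstack([proj, np.zeros((mu.shape[0], 2 - n_comp))])
        evr = np.concatenate([evr, np.zeros(2 - n_comp)])
    return proj, evr
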