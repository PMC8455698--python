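"""The angle-attention graph network.

Architecture (encoder → decoder):

1. *Bond message passing* over the chemical-bond graph.  Each directed
   bond w→v carries an edge-state matrix e_vw ∈ R^{d×d/2} and a scalar
   *bond-angle attention* weight

       attn = Σ_i (A'·cos²θ_i + B'·cosθ_i + C') / M,

   the mean Karplus-form term over the M angles θ_i between the bond and
   its neighbouring bonds at the head atom; A', B', C' are three global
   learnable scalars.  The node update is residual:
   h_v ← Σ_w attn · rowsum(Conv(h_w) ⊙ e_vw) + h_v, where Conv is a
   zero-padded sliding-window unfold followed by a learned position-wise
   linear map.
2. *Coupling message passing* over the graph whose edges are the labelled
   coupled pairs — same update without the attention factor.
3. *Multi-head self-attention* over each molecule's coupled atoms:
   softmax(QKᵀ/√d_model)V per head, heads concatenated and mixed by W.
4. *MLP decoder* on f_atom0 ⊕ f_atom1 ⊕ f_mol (widths d + d + d/2).

The training criterion is the grouped log(MAE) over coupling types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .autodiff import (
    Tensor,
    concat,
    gather_rows,
    parameter,
    segment_sum,
    softmax_last,
    unfold,
    uniform_fan_in,
)

#: Attention coefficients (A', B', C') as learned at full scale; used to
#: initialise the three global scalars.
DEFAULT_ATTENTION_COEFFS: tuple[float, float, float] = (0.12, 0.99, 0.27)


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    ``d_model`` must be even and divisible by ``n_heads``.  ``n_passes``
    is the number T of (bond MP, coupling MP) iterations applied before
    self-attention.  ``attention_scale`` chooses the softmax temperature:
    ``"d_model"`` scales scores by √d_model, ``"d_head"`` by √(d_model/h).
    """

    d_model: int = 128
    n_heads: int = 8
    n_passes: int = 2
    hidden_sizes: tuple[int, ...] = (256, 128)
    attention_scale: str = "d_model"
    use_angle_attention: bool = True
    use_angle_features: bool = True
    log_mae_floor: float = 1e-9

    def __post_init__(self) -> None:
        if self.d_model % 2 != 0:
            raise ValueError("d_model must be even")
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.attention_scale not in ("d_model", "d_head"):
            raise ValueError("attention_scale must be 'd_model' or 'd_head'")

    @property
    def d_edge(self) -> int:
        return self.d_model // 2

    @property
    def softmax_scale(self) -> float:
        if self.attention_scale == "d_model":
            return float(np.sqrt(self.d_model))
        return float(np.sqrt(self.d_model // self.n_heads))


# ---------------------------------------------------------------------------
# angle attention
# ---------------------------------------------------------------------------


def angle_attention(
    theta_list_deg: Sequence[float],
    coeffs: Sequence[float] = DEFAULT_ATTENTION_COEFFS,
) -> float:
    """Bond-angle attention weight for one directed bond (plain numpy).

    ``theta_list_deg`` holds the angles (degrees) between the bond and
    each neighbouring bond at its head atom.  A terminal bond with no
    neighbours (M = 0) gets the neutral weight 1.
    """
    thetas = np.asarray(theta_list_deg, dtype=float)
    if thetas.size == 0:
        return 1.0
    a, b, c = (float(x) for x in coeffs)
    cos = np.cos(np.radians(thetas))
    return float(np.mean(a * cos**2 + b * cos + c))


def edge_attention(
    cos_thetas: np.ndarray,
    angle_edge: np.ndarray,
    n_edges: int,
    coeffs: Tensor,
) -> Tensor:
    """Differentiable per-edge attention from flattened neighbour angles.

    ``cos_thetas`` are cos θ values for all edges concatenated and
    ``angle_edge`` maps each entry to its directed-edge index.  Edges with
    no neighbouring bonds receive the neutral weight 1.
    """
    dtype = coeffs.data.dtype
    counts = np.bincount(np.asarray(angle_edge, dtype=int), minlength=n_edges)
    c = Tensor(np.asarray(cos_thetas, dtype=dtype))
    a_ = gather_rows(coeffs, np.array([0]))
    b_ = gather_rows(coeffs, np.array([1]))
    c_ = gather_rows(coeffs, np.array([2]))
    terms = a_ * c * c + b_ * c + c_
    sums = segment_sum(terms, angle_edge, n_edges)
    attn = sums * Tensor((1.0 / np.maximum(counts, 1.0)).astype(dtype)) + Tensor(
        (counts == 0).astype(dtype)
    )
    return attn


# ---------------------------------------------------------------------------
# message passing
# ---------------------------------------------------------------------------


def conv_unfold(
    h: Tensor, window: int, weight: Optional[Tensor] = None, bias: Optional[Tensor] = None
) -> Tensor:
    """Conv(·): sliding-window unfold of node vectors to edge-matrix shape.

    Input (n, d) → (n, d, window) with rows ``h[r:r+window]`` zero-padded
    past the end, then an optional learned position-wise linear map
    (window → window) applied to each row.
    """
    u = unfold(h, window)
    if weight is not None:
        u = u @ weight
        if bias is not None:
            u = u + bias
    return u


def mp_step(
    h: Tensor,
    src: np.ndarray,
    dst: np.ndarray,
    edge_states: Tensor,
    conv_w: Tensor,
    conv_b: Tensor,
    attn: Optional[Tensor] = None,
) -> Tensor:
    """One residual message-passing update over directed edges.

    Message of edge w→v: attn · rowsum-over-columns(Conv(h_w) ⊙ e_vw),
    a d_model vector; messages are summed into the head atom and added to
    its previous state.  Atoms with no incident edges pass through
    unchanged.
    """
    n, d = h.shape
    window = edge_states.shape[-1]
    hw = gather_rows(h, src)
    u = conv_unfold(hw, window, conv_w, conv_b)
    msg = (u * edge_states).sum(axis=2)
    if attn is not None:
        msg = msg * attn.reshape(-1, 1)
    return h + segment_sum(msg, dst, n)


def bond_mp_step(
    h: Tensor,
    src: np.ndarray,
    dst: np.ndarray,
    edge_states: Tensor,
    conv_w: Tensor,
    conv_b: Tensor,
    attn: Tensor,
) -> Tensor:
    """Bond message passing (with angle attention)."""
    return mp_step(h, src, dst, edge_states, conv_w, conv_b, attn=attn)


def coupling_mp_step(
    h: Tensor,
    src: np.ndarray,
    dst: np.ndarray,
    edge_states: Tensor,
    conv_w: Tensor,
    conv_b: Tensor,
) -> Tensor:
    """Coupling message passing — identical update with no attention factor."""
    return mp_step(h, src, dst, edge_states, conv_w, conv_b, attn=None)


# ---------------------------------------------------------------------------
# self-attention
# ---------------------------------------------------------------------------


def scaled_dot_attention(
    q: Tensor,
    k: Tensor,
    v: Tensor,
    mask: Optional[np.ndarray] = None,
    scale: Optional[float] = None,
) -> tuple[Tensor, Tensor]:
    """softmax(QKᵀ/scale)V over the last two axes; returns (output, weights).

    ``mask`` (broadcastable to the score shape, 1 = valid key) restricts
    attention to each molecule's own tokens.
    """
    if scale is None:
        scale = float(np.sqrt(q.shape[-1]))
    scores = (q @ k.mT) * (1.0 / scale)
    weights = softmax_last(scores, mask=mask)
    return weights @ v, weights


def multi_head_attention(
    tokens: Tensor,
    wq: Tensor,
    wk: Tensor,
    wv: Tensor,
    wo: Tensor,
    n_heads: int,
    mask: Optional[np.ndarray] = None,
    scale: Optional[float] = None,
) -> Tensor:
    """Multi-head self-attention over token sets.

    ``tokens`` is (..., L, d_model); the d_model columns of the Q/K/V
    projections are split into ``n_heads`` independent heads of width
    d_model/h, attended separately, concatenated and mixed by ``wo``.
    """
    *batch, L, d = tokens.shape
    if d % n_heads != 0:
        raise ValueError("token width must be divisible by n_heads")
    dh = d // n_heads

    def split(x: Tensor) -> Tensor:
        # (..., L, d) -> (..., h, L, dh)
        x = x.reshape(tuple(batch) + (L, n_heads, dh))
        axes = tuple(range(len(batch))) + (
            len(batch) + 1,
            len(batch),
            len(batch) + 2,
        )
        return x.transpose(axes)

    q, k, v = split(tokens @ wq), split(tokens @ wk), split(tokens @ wv)
    head_mask = None
    if mask is not None:
        # (..., L) valid-token mask -> (..., 1, 1, L) key mask per head
        head_mask = np.asarray(mask).astype(bool)[..., None, None, :]
    out, _ = scaled_dot_attention(q, k, v, mask=head_mask, scale=scale)
    # (..., h, L, dh) -> (..., L, d)
    axes = tuple(range(len(batch))) + (len(batch) + 1, len(batch), len(batch) + 2)
    out = out.transpose(axes).reshape(tuple(batch) + (L, d))
    return out @ wo


# ---------------------------------------------------------------------------
# embedding + decoder
# ---------------------------------------------------------------------------


def embed(
    raw: Tensor | np.ndarray,
    weight: Tensor,
    bias: Tensor,
    matrix_shape: Optional[tuple[int, int]] = None,
) -> Tensor:
    """Linear embedding of raw feature rows.

    With ``matrix_shape=(d, w)`` the output rows (length d·w) are reshaped
    row-major into edge-state matrices: element (r, c) comes from output
    slot r·w + c.
    """
    x = raw if isinstance(raw, Tensor) else Tensor(raw)
    out = x @ weight + bias
    if matrix_shape is not None:
        d, w = matrix_shape
        out = out.reshape((-1, d, w))
    return out


def decode_scc(
    f_atom0: Tensor,
    f_atom1: Tensor,
    f_mol: Tensor,
    mlp_params: Sequence[tuple[Tensor, Tensor]],
) -> Tensor:
    """MLP regression head on f_atom0 ⊕ f_atom1 ⊕ f_mol → SCC (Hz).

    Hidden layers use ReLU; the final layer is affine.  The concatenation
    is ordered, so swapping the two atoms changes the prediction — the
    canonical H-first record ordering keeps inputs consistent.
    """
    z = concat([f_atom0, f_atom1, f_mol], axis=-1)
    for i, (w, b) in enumerate(mlp_params):
        z = z @ w + b
        if i < len(mlp_params) - 1:
            z = z.relu()
    return z.reshape((-1,))


# ---------------------------------------------------------------------------
# parameters + full forward pass
# ---------------------------------------------------------------------------


def init_params(
    rng: np.random.Generator,
    n_atom_feats: int,
    n_bond_feats: int,
    n_coupling_feats: int,
    n_mol_feats: int,
    config: ModelConfig,
) -> dict[str, Tensor]:
    """Initialise all trainable tensors (uniform fan-in scaling)."""
    d, w = config.d_model, config.d_edge
    p: dict[str, Tensor] = {}
    p["atom_embed_W"] = uniform_fan_in(rng, (n_atom_feats, d))
    p["atom_embed_b"] = parameter(np.zeros(d))
    p["bond_embed_W"] = uniform_fan_in(rng, (n_bond_feats, d * w))
    p["bond_embed_b"] = parameter(np.zeros(d * w))
    p["cpl_embed_W"] = uniform_fan_in(rng, (n_coupling_feats, d * w))
    p["cpl_embed_b"] = parameter(np.zeros(d * w))
    p["mol_embed_W"] = uniform_fan_in(rng, (n_mol_feats, w))
    p["mol_embed_b"] = parameter(np.zeros(w))
    # conv maps start small: the residual path dominates early training
    p["conv_bond_W"] = uniform_fan_in(rng, (w, w), fan_in=w * d)
    p["conv_bond_b"] = parameter(np.zeros(w))
    p["conv_cpl_W"] = uniform_fan_in(rng, (w, w), fan_in=w * d)
    p["conv_cpl_b"] = parameter(np.zeros(w))
    p["attn_coeffs"] = parameter(np.array(DEFAULT_ATTENTION_COEFFS))
    for name in ("Wq", "Wk", "Wv", "Wo"):
        p[name] = uniform_fan_in(rng, (d, d))
    widths = (2 * d + w,) + tuple(config.hidden_sizes) + (1,)
    for i, (win, wout) in enumerate(zip(widths[:-1], widths[1:])):
        p[f"mlp_W{i}"] = uniform_fan_in(rng, (win, wout))
        p[f"mlp_b{i}"] = parameter(np.zeros(wout))
    return p


def mlp_layers(params: dict[str, Tensor]) -> list[tuple[Tensor, Tensor]]:
    layers = []
    i = 0
    while f"mlp_W{i}" in params:
        layers.append((params[f"mlp_W{i}"], params[f"mlp_b{i}"]))
        i += 1
    return layers


def forward(
    batch,
    params: dict[str, Tensor],
    config: ModelConfig,
    return_embeddings: bool = False,
):
    """Full pipeline: embed → T×(bond MP, coupling MP) → self-attention → decode.

    ``batch`` is a :class:`jcouple.features.Batch`.  Returns the predicted
    SCCs as a Tensor of shape (n_records,), plus a dict of intermediate
    representations when ``return_embeddings`` is set.
    """
    d, w = config.d_model, config.d_edge
    h = embed(batch.atom_x, params["atom_embed_W"], params["atom_embed_b"])
    e_bond = embed(
        batch.bond_x, params["bond_embed_W"], params["bond_embed_b"], matrix_shape=(d, w)
    )
    e_cpl = embed(
        batch.cpl_x, params["cpl_embed_W"], params["cpl_embed_b"], matrix_shape=(d, w)
    )
    n_bond_edges = len(batch.bond_src)
    if config.use_angle_attention:
        attn = edge_attention(
            batch.angle_cos, batch.angle_edge, n_bond_edges, params["attn_coeffs"]
        )
    else:
        attn = Tensor(np.ones(n_bond_edges, dtype=h.data.dtype))
    for _ in range(config.n_passes):
        if n_bond_edges:
            h = bond_mp_step(
                h,
                batch.bond_src,
                batch.bond_dst,
                e_bond,
                params["conv_bond_W"],
                params["conv_bond_b"],
                attn,
            )
        if len(batch.cpl_src):
            h = coupling_mp_step(
                h,
                batch.cpl_src,
                batch.cpl_dst,
                e_cpl,
                params["conv_cpl_W"],
                params["conv_cpl_b"],
            )
    # tokens: each molecule's coupled atoms, padded to the batch max
    tok = gather_rows(h, batch.tokens)  # (B, L, d)
    f_atom = multi_head_attention(
        tok,
        params["Wq"],
        params["Wk"],
        params["Wv"],
        params["Wo"],
        config.n_heads,
        mask=batch.token_mask,
        scale=config.softmax_scale,
    )
    f_flat = f_atom.reshape((-1, d))
    f0 = gather_rows(f_flat, batch.rec_tok0)
    f1 = gather_rows(f_flat, batch.rec_tok1)
    f_mol = embed(batch.mol_x, params["mol_embed_W"], params["mol_embed_b"])
    f_mol_rec = gather_rows(f_mol, batch.rec_mol)
    pred = decode_scc(f0, f1, f_mol_rec, mlp_layers(params))
    if return_embeddings:
        aux = {
            "node_states": h,
            "f_atom": f_atom,
            "record_embedding": concat([f0, f1, f_mol_rec], axis=-1),
        }
        return pred, aux
    return pred


def loss_grouped_log_mae(
    pred: Tensor, y: np.ndarray, type_ids: np.ndarray, floor: float = 1e-9
) -> Tensor:
    """Differentiable grouped log(MAE): mean over present types of ln(MAE_t)."""
    type_ids = np.asarray(type_ids, dtype=int)
    uniq, compact = np.unique(type_ids, return_inverse=True)
    dtype = pred.data.dtype
    counts = np.bincount(compact)
    err = (pred - Tensor(np.asarray(y, dtype=dtype))).abs()
    mae_t = segment_sum(err, compact, len(uniq)) * Tensor((1.0 / counts).astype(dtype))
    return mae_t.clip_min(floor).log().mean()


def loss_mae(pred: Tensor, y: np.ndarray) -> Tensor:
    """Plain pooled mean absolute error (alternative training loss)."""
    return (pred - Tensor(np.asarray(y, dtype=pred.data.dtype))).abs().mean()
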