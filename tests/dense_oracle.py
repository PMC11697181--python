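"""Independent dense, loop-based re-implementation of the forward pass.

Used only as a test oracle: everything is dense numpy with explicit Python
loops for the matrix products, no sparsity, no shared code with the package's
compute path.
"""

import numpy as np


def loop_matmul(A, B):
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    out = np.zeros((A.shape[0], B.shape[1]))
    for i in range(A.shape[0]):
        for j in range(B.shape[1]):
            s = 0.0
            for k in range(A.shape[1]):
                s += A[i, k] * B[k, j]
            out[i, j] = s
    return out


def dense_normalize(A):
    """D~^{-1/2} (A + I) D~^{-1/2} computed entrywise."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    A_hat = A + np.eye(n)
    deg = A_hat.sum(axis=1)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = A_hat[i, j] / np.sqrt(deg[i] * deg[j])
    return out


def dense_log_softmax(Z):
    Z = np.asarray(Z, dtype=float)
    out = np.zeros_like(Z)
    for i in range(Z.shape[0]):
        m = Z[i].max()
        out[i] = (Z[i] - m) - np.log(np.exp(Z[i] - m).sum())
    return out


def dense_forward_logp(A, X, weights, config):
    """Two-branch forward pass from raw dense inputs.

    `weights` maps parameter names (W0, W1..WL, A_W1, A_b1, A_W2, A_b2,
    X_W1, X_b1, X_W2, X_b2, Wprime) to plain numpy arrays.
    """
    A = np.asarray(A, dtype=float)
    X = np.asarray(X, dtype=float)
    A_norm = dense_normalize(A)

    # RS graph encoder
    r = loop_matmul(X, weights["W0"])
    heads = []
    for layer in range(1, config.num_layers + 1):
        r1 = loop_matmul(A_norm, r)
        r2 = loop_matmul(A_norm, r1)
        r = np.maximum(np.concatenate([r1, r2], axis=1), 0.0)
        heads.append(loop_matmul(r, weights[f"W{layer}"]))
    h_G = np.concatenate(heads, axis=1)
    if config.eq5_logsoftmax:
        h_G = dense_log_softmax(h_G)

    # bimodal extractor
    h_A = loop_matmul(
        np.maximum(loop_matmul(A, weights["A_W1"]) + weights["A_b1"], 0.0),
        weights["A_W2"]) + weights["A_b2"]
    h_X = loop_matmul(
        np.maximum(loop_matmul(X, weights["X_W1"]) + weights["X_b1"], 0.0),
        weights["X_W2"]) + weights["X_b2"]
    h_BI = config.alpha * h_A + config.beta * h_X

    logits = loop_matmul(h_G + h_BI, weights["Wprime"])
    return dense_log_softmax(logits)
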