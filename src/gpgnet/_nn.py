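"""Minimal dense neural-network primitives with explicit backpropagation.

Forward functions return ``(output, cache)``; backward functions take the
upstream gradient plus the cache and return input/parameter gradients.
Everything is plain float64 NumPy, so repeated runs are bit-identical.
"""

from __future__ import annotations

import numpy as np


def init_linear(rng: np.random.Generator, fan_out: int, fan_in: int):
    """Uniform fan-in initialization: W ~ U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(fan_in)
    W = rng.uniform(-bound, bound, size=(fan_out, fan_in))
    b = rng.uniform(-bound, bound, size=fan_out)
    return W, b


# -- linear: y = x @ W.T + b, x of shape (..., fan_in) ----------------------

def linear_forward(x, W, b):
    return x @ W.T + b, x


def linear_backward(grad, cache, W):
    x = cache
    g2 = grad.reshape(-1, grad.shape[-1])
    x2 = x.reshape(-1, x.shape[-1])
    dW = g2.T @ x2
    db = g2.sum(axis=0)
    dx = grad @ W
    return dx, dW, db


# -- ReLU -------------------------------------------------------------------

def relu_forward(x):
    mask = x > 0
    return x * mask, mask


def relu_backward(grad, mask):
    return grad * mask


# -- 1-D convolution over axis 1: x (N, L, C_in) -> (N, T, C_out) -----------

def conv1d_forward(x, W, b, stride):
    """W has shape (C_out, K, C_in); valid padding, given stride."""
    N, L, C_in = x.shape
    C_out, K, _ = W.shape
    T = (L - K) // stride + 1
    idx = np.arange(T)[:, None] * stride + np.arange(K)[None, :]
    patches = x[:, idx, :].reshape(N, T, K * C_in)
    y = patches @ W.reshape(C_out, -1).T + b
    return y, (patches, x.shape, idx)


def conv1d_backward(grad, cache, W, stride):
    patches, x_shape, idx = cache
    N, L, C_in = x_shape
    C_out, K, _ = W.shape
    T = grad.shape[1]
    g2 = grad.reshape(-1, C_out)
    dW = (g2.T @ patches.reshape(-1, K * C_in)).reshape(C_out, K, C_in)
    db = g2.sum(axis=0)
    dpatch = (grad @ W.reshape(C_out, -1)).reshape(N, T, K, C_in)
    dx = np.zeros(x_shape)
    for j in range(K):  # K is small; scatter strided slices
        dx[:, j : j + T * stride : stride, :] += dpatch[:, :, j, :]
    return dx, dW, db


# -- global max pooling over axis 1 -----------------------------------------

def maxpool_forward(x):
    arg = x.argmax(axis=1)
    N, _, C = x.shape
    y = x[np.arange(N)[:, None], arg, np.arange(C)[None, :]]
    return y, (arg, x.shape)


def maxpool_backward(grad, cache):
    arg, shape = cache
    N, _, C = shape
    dx = np.zeros(shape)
    dx[np.arange(N)[:, None], arg, np.arange(C)[None, :]] = grad
    return dx


# -- softmax cross-entropy ---------------------------------------------------

def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits, labels, eps=1e-12):
    """Mean negative log-probability of the true class, with gradient.

    ``eps`` floors the probability inside the log for numerical safety.
    Returns ``(loss, dlogits)`` where dlogits is the batch-mean gradient.
    """
    p = softmax(logits)
    N = logits.shape[0]
    loss = -np.mean(np.log(np.maximum(p[np.arange(N), labels], eps)))
    dlogits = p.copy()
    dlogits[np.arange(N), labels] -= 1.0
    return loss, dlogits / N


# -- Adam --------------------------------------------------------------------

class Adam:
    """Adam optimizer over a dict of named parameter arrays (in place)."""

    def __init__(self, params: dict, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, g in grads.items():
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1**self.t)
            vhat = self.v[key] / (1 - b2**self.t)
            self.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
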