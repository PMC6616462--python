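"""Loop-based reference implementation of the shrunken-centroid classifier.

Deliberately written with explicit Python loops and no shared code with the
package, so it can serve as an independent oracle for the engine with the
neighbourhood adjustment switched off (balanced overall centroid,
m_k = sqrt(1/n_k + 1/n), pooled SD divisor n - K, equal priors).
"""

import math

import numpy as np


class ReferenceNSC:
    def __init__(self, X, y):
        """X: p features x n samples; y: group label per sample."""
        X = np.asarray(X, dtype=float)
        p, n = X.shape
        labels = sorted(set(y))
        K = len(labels)
        class_means = np.zeros((p, K))
        counts = []
        for k, g in enumerate(labels):
            cols = [j for j in range(n) if y[j] == g]
            counts.append(len(cols))
            for i in range(p):
                class_means[i, k] = sum(X[i, j] for j in cols) / len(cols)
        overall = np.zeros(p)
        for i in range(p):
            overall[i] = sum(class_means[i, k] for k in range(K)) / K
        s = np.zeros(p)
        for i in range(p):
            ss = 0.0
            for k, g in enumerate(labels):
                for j in range(n):
                    if y[j] == g:
                        ss += (X[i, j] - class_means[i, k]) ** 2
            s[i] = math.sqrt(ss / (n - K))
        s0 = float(np.median(s))
        m = [math.sqrt(1.0 / counts[k] + 1.0 / n) for k in range(K)]
        d = np.zeros((p, K))
        for i in range(p):
            for k in range(K):
                d[i, k] = (class_means[i, k] - overall[i]) / (m[k] * (s[i] + s0))
        group_max = np.array([max(abs(d[i, k]) for i in range(p)) for k in range(K)])
        self.labels, self.K, self.n = labels, K, n
        self.counts, self.m, self.s, self.s0 = counts, m, s, s0
        self.class_means, self.overall, self.d = class_means, overall, d
        self.group_max = group_max
        self.delta_max = float(group_max.mean())
        self.grid = np.linspace(0.0, self.delta_max, 30)

    def d_prime(self, delta):
        p, K = self.d.shape
        out = np.zeros((p, K))
        for k in range(K):
            dk = (delta / self.delta_max) * self.group_max[k] if self.delta_max > 0 else 0.0
            for i in range(p):
                v = abs(self.d[i, k]) - dk
                out[i, k] = (1 if self.d[i, k] > 0 else -1 if self.d[i, k] < 0 else 0) * max(0.0, v)
        return out

    def centroids(self, delta):
        dp = self.d_prime(delta)
        p, K = dp.shape
        cent = np.zeros((p, K))
        for i in range(p):
            for k in range(K):
                cent[i, k] = self.overall[i] + self.m[k] * (self.s[i] + self.s0) * dp[i, k]
        return cent

    def classify(self, Xnew, delta):
        """Returns (labels, discriminant scores, posteriors) for columns of Xnew."""
        Xnew = np.asarray(Xnew, dtype=float)
        cent = self.centroids(delta)
        p, K = cent.shape
        n_new = Xnew.shape[1]
        disc = np.zeros((n_new, K))
        for j in range(n_new):
            for k in range(K):
                acc = 0.0
                for i in range(p):
                    acc += (Xnew[i, j] - cent[i, k]) ** 2 / (self.s[i] + self.s0) ** 2
                disc[j, k] = acc - 2.0 * math.log(1.0 / K)
        labels = [self.labels[int(np.argmin(disc[j]))] for j in range(n_new)]
        post = np.zeros((n_new, K))
        for j in range(n_new):
            mx = max(-0.5 * disc[j, k] for k in range(K))
            w = [math.exp(-0.5 * disc[j, k] - mx) for k in range(K)]
            tot = sum(w)
            for k in range(K):
                post[j, k] = w[k] / tot
        return labels, disc, post
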