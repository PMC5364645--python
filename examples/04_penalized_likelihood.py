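"""Hub-aware sparse precision estimation by penalized likelihood.

The likelihood route estimates the precision matrix Ω directly by
maximizing log|Ω| − tr(SΩ) minus an elementwise ℓ1 penalty that is
reduced to αλ on hub-adjacent entries.  Support sparsity is monotone in
λ; the hub relaxation recovers more hub edges at equal λ.
"""

import numpy as np

from espace import (
    HubSet,
    eglasso_fit,
    generate_precision,
    hub_network,
    precision_to_covariance,
    preprocess,
    sample_covariance,
    sample_expression,
)

net = hub_network(p=25, n_hubs=2, seed=21)
Omega_true = generate_precision(net, seed=22)
X = preprocess(sample_expression(precision_to_covariance(Omega_true), n=100, seed=23),
               scale=False)
S = sample_covariance(X)

iu, ju = np.triu_indices(25, 1)
hub_mask = net.hubs.mask(25)
hub_adj = hub_mask[iu] | hub_mask[ju]

print("lambda   edges(alpha=1)  edges(alpha=0.5)  hub edges(alpha=1 -> 0.5)")
for lam in (0.05, 0.1, 0.2, 0.4):
    plain = eglasso_fit(S, net.hubs, lam=lam, alpha=1.0)
    relaxed = eglasso_fit(S, net.hubs, lam=lam, alpha=0.5)
    nz_p = np.abs(plain.Omega[iu, ju]) > 1e-10
    nz_r = np.abs(relaxed.Omega[iu, ju]) > 1e-10
    print(f"{lam:5.2f}   {nz_p.sum():9d}  {nz_r.sum():15d}  "
          f"{(nz_p & hub_adj).sum():8d} -> {(nz_r & hub_adj).sum():d}")

print(f"\ntrue network: {net.n_edges} edges, "
      f"{int(hub_adj[[np.flatnonzero((iu==a)&(ju==b))[0] for a,b in sorted(net.edges)]].sum())}"
      " of them hub-adjacent")
print("Raising lambda prunes edges everywhere; lowering alpha restores"
      "\nhub-adjacent ones first, which is the point of the hub prior.")
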