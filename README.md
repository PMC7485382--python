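# vfspace

A vector-space model of word production in verbal fluency (VF) tasks, for
researchers in computational neuroscience and psycholinguistics who study
retrieval time courses and combinatorial network connectivity.

## The model

Two empirical power-of-two laws describe the connectivity underlying
retrieval: the set of all non-ordered tuples over *i* items, N = 2^i
(including the empty tuple), which explains the logarithmic VF time
course, and N = 2^i − 1 neural cliques per connectivity motif, which
excludes the inactive state. `vfspace` represents both on one state
space: the tuples are orthonormal basis vectors |αβ…⟩ (one binary digit
per item), and the network configuration is a unit state vector
|x⟩ = Σ c_k |tuple_k⟩ with Σ|c_k|² = 1.

Producing a word w zeroes the coefficients of every tuple containing w
while conserving the norm — an orthogonal rotation R_w, built from the
single 2×2 minimal matrix ρ = (1/√2)[[1, 1], [−1, 1]] acting on each
(without-w, with-w) coordinate pair. All R_w over a basis commute and
share the eigenvalues e^{±iπ/4} at multiplicity 2^(i−1): one elementary
operation, analogous to a quantum logic gate, drives the whole production
sequence from the uniform initial state to the inactive (empty-tuple)
state.

The time-course side implements the fused Bousfieldian function
n(t) = c·[1 − (1 + αrt/c)^(−1/α)], its exponential (α → 0), hyperbolic
(α = 1) and logarithmic (α → ∞, k = c/α fixed) special cases, and the
retrieval-probability law p_{n+1} = n′(t_n)/r, which for the logarithmic
curve is the geometric sequence e^{−n/k}. A sampling-with-replacement
simulator closes the loop: drawing tuples uniformly with replacement
yields stage-n success probability 2^(−n) and hence logarithmic cumulative
curves, which `vfspace.fit` recovers by least squares with AICc model
selection. See `docs/methods.md` for assumptions and numerical choices.

## Worked example

The three-item basis over {A, B, C} and the full production chain:

```pycon
>>> import numpy as np, vfspace as v
>>> basis = v.build_basis(["A", "B", "C"])
>>> print(basis.to_frame().to_string(index=False))
tuple_label bitstring  decimal
          ∅       000        0
        {A}       100        1
        {B}       010        2
      {A,B}       110        3
        {C}       001        4
      {A,C}       101        5
      {B,C}       011        6
    {A,B,C}       111        7
>>> x = v.uniform_state(basis)          # all coefficients 1/sqrt(8)
>>> for w, st in zip("CBA", v.apply_sequence(basis, ["C", "B", "A"], x)):
...     print(w, np.round(st.coefficients, 6))
C [0.5 0.5 0.5 0.5 0.  0.  0.  0. ]
B [0.707107 0.707107 0.       0.       0.       0.       0.       0.      ]
A [1. 0. 0. 0. 0. 0. 0. 0.]
```

Producing C zeroes the four C-containing tuples and renormalizes the
survivors to 1/2; after the last word only the empty tuple remains, with
coefficient 1 — every intermediate state has Σ|c_k|² = 1. The retrieval
probabilities of the matching logarithmic curve halve with each word:

```pycon
>>> v.retrieval_probabilities(v.LogParams(k=1/np.log(2), r=1.0), 5)
array([1.    , 0.5   , 0.25  , 0.125 , 0.0625])
```

Simulating 500 runs of a 12-word category at one draw per second and
fitting the averaged curve recovers the predicted shape parameter
k = 1/ln 2 ≈ 1.4427:

```pycon
>>> cfg = v.SimulationConfig(i=12, r=1.0, n_runs=500, seed=42)
>>> onsets = np.array([rec.onsets for rec in v.simulate_many(cfg)])
>>> fit = v.fit(onsets.mean(axis=0), candidates=("fbf", "logarithmic"))
>>> round(fit.params.k, 3)
1.535
```

(The fitted rate comes back as r/ln 2 rather than r — an exact
discreteness effect of the coarse success ratio q = 1/2, derived in
`docs/methods.md`.)

The same workflows are available from the shell:

```sh
vfspace basis --items A,B,C
vfspace rotate --items A,B,C --produce C,B,A
vfspace simulate --items 12 --rate 1 --runs 500 --seed 42 --out runs/
vfspace fit runs/run_0000.csv --report fit.json
vfspace probabilities --model logarithmic --k 1.4427 --r 1 --n-max 10
```

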