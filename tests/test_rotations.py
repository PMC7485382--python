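"""Production rotations: minimal matrix, worked-example chain, spectra."""

import itertools
import math

import numpy as np
import pytest

from vfspace import (
    apply,
    apply_sequence,
    build_basis,
    minimal_matrix,
    production_operator,
    similar,
    spectrum,
    uniform_state,
    xbar_state,
)


def test_minimal_matrix_value_and_action():
    rho = minimal_matrix()
    assert np.allclose(rho, np.array([[1, 1], [-1, 1]]) / math.sqrt(2))
    # the single-item production event: equal superposition -> (1, 0)
    assert np.allclose(rho @ (np.ones(2) / math.sqrt(2)), [1.0, 0.0])
    assert np.allclose(rho.T @ rho, np.eye(2), atol=1e-15)
    assert np.linalg.det(rho) == pytest.approx(1.0)
    # a 45-degree rotation: eighth power is the identity
    assert np.allclose(np.linalg.matrix_power(rho, 8), np.eye(2), atol=1e-12)


def test_minimal_matrix_eigenvalues():
    eig = np.sort_complex(np.linalg.eigvals(minimal_matrix()))
    expected = np.sort_complex([np.exp(1j * np.pi / 4), np.exp(-1j * np.pi / 4)])
    assert np.allclose(eig, expected, atol=1e-12)


def test_production_chain_worked_example(abc_basis, abc_uniform):
    """R_C|x> = |x_C>, R_B|x_C> = |x_B>, R_A|x_B> = |000> with unit norms."""
    xc = apply(production_operator(abc_basis, "C"), abc_uniform)
    assert np.allclose(xc.coefficients, [0.5, 0.5, 0.5, 0.5, 0, 0, 0, 0], atol=1e-12)
    xb = apply(production_operator(abc_basis, "B"), xc)
    s = 1 / math.sqrt(2)
    assert np.allclose(xb.coefficients, [s, s, 0, 0, 0, 0, 0, 0], atol=1e-12)
    xa = apply(production_operator(abc_basis, "A"), xb)
    assert np.allclose(xa.coefficients, [1, 0, 0, 0, 0, 0, 0, 0], atol=1e-12)
    for state in (xc, xb, xa):
        assert state.norm_squared() == pytest.approx(1.0, abs=1e-12)


def test_apply_sequence_trajectory(abc_basis, abc_uniform):
    traj = apply_sequence(abc_basis, ["C", "B", "A"], abc_uniform)
    assert len(traj) == 3
    assert np.allclose(traj[0].coefficients, [0.5, 0.5, 0.5, 0.5, 0, 0, 0, 0])
    assert np.allclose(traj[-1].coefficients, [1, 0, 0, 0, 0, 0, 0, 0], atol=1e-12)
    assert apply_sequence(abc_basis, [], abc_uniform) == []
    with pytest.raises(ValueError):
        apply_sequence(abc_basis, ["A", "A"], abc_uniform)


def test_every_order_reaches_the_inactive_state(abc_basis, abc_uniform):
    """Operators commute, so all six production orders end in |000>."""
    for order in itertools.permutations(["A", "B", "C"]):
        final = apply_sequence(abc_basis, order, abc_uniform)[-1]
        assert np.allclose(final.coefficients, [1, 0, 0, 0, 0, 0, 0, 0], atol=1e-12)


def test_rotation_on_a_free_items(abc_basis, abc_uniform):
    xa = apply(production_operator(abc_basis, "A"), abc_uniform)
    expected = np.array([0.5, 0, 0.5, 0, 0.5, 0, 0.5, 0])
    assert np.allclose(xa.coefficients, expected, atol=1e-12)


def test_same_rotation_acts_on_the_inseparable_state(abc_basis):
    """The identical R_C applies to |x-bar>, conserving the norm; its
    action agrees with the explicit matrix product."""
    op = production_operator(abc_basis, "C")
    xb = xbar_state(abc_basis)
    out = apply(op, xb)
    assert out.norm_squared() == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(out.coefficients, op.matrix @ xb.coefficients, atol=1e-12)


def test_orthogonality_and_norm_conservation():
    rng = np.random.default_rng(7)
    for i in range(1, 7):
        labels = [f"w{j}" for j in range(i)]
        basis = build_basis(labels)
        for w in labels:
            op = production_operator(basis, w)
            mat = op.matrix
            assert np.max(np.abs(mat.T @ mat - np.eye(2**i))) < 1e-12
            for _ in range(10):
                v = rng.standard_normal(2**i)
                v /= np.linalg.norm(v)
                out = op.apply_to_coefficients(v)
                assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)
                # transpose undoes the rotation
                assert np.allclose(mat.T @ out, v, atol=1e-12)


def test_blockwise_equals_kronecker_oracle():
    """The blockwise construction equals identity-factors (x) rho at the
    produced item's position, assembled independently with np.kron."""
    rho = minimal_matrix()
    eye = np.eye(2)
    for i in range(1, 5):
        labels = [f"w{j}" for j in range(i)]
        basis = build_basis(labels)
        for bit, w in enumerate(labels):
            expected = np.array([[1.0]])
            for b in reversed(range(i)):  # LSB is the last Kronecker factor
                expected = np.kron(expected, rho if b == bit else eye)
            assert np.max(np.abs(production_operator(basis, w).matrix - expected)) < 1e-12


def test_operators_commute():
    basis = build_basis(["A", "B", "C", "D"])
    for w1, w2 in itertools.combinations(basis.items, 2):
        m1 = production_operator(basis, w1).matrix
        m2 = production_operator(basis, w2).matrix
        assert np.allclose(m1 @ m2, m2 @ m1, atol=1e-12)


def test_shared_spectrum_single_equivalence_class():
    """For every i <= 6 the i operators share one eigenvalue multiset: that
    of rho at multiplicity 2^(i-1)."""
    for i in range(1, 7):
        labels = [f"w{j}" for j in range(i)]
        basis = build_basis(labels)
        spectra = {tuple(spectrum(production_operator(basis, w))) for w in labels}
        assert len(spectra) == 1
        eig = spectrum(production_operator(basis, labels[0]))
        root = math.sqrt(0.5)
        plus = np.sum(np.isclose(eig, root + 1j * root, atol=1e-9))
        minus = np.sum(np.isclose(eig, root - 1j * root, atol=1e-9))
        assert plus == minus == 2 ** (i - 1)


def test_similar_examples(abc_basis):
    ra = production_operator(abc_basis, "A")
    rb = production_operator(abc_basis, "B")
    assert similar(ra, rb)
    assert similar(ra, ra)
    other = production_operator(build_basis(["A", "B"]), "A")
    with pytest.raises(ValueError):
        similar(ra, other)


def test_validation(abc_basis, abc_uniform):
    with pytest.raises(ValueError):
        production_operator(abc_basis, "Z")
    with pytest.raises(ValueError):
        production_operator(build_basis(["A"], include_empty=False), "A")
    op = production_operator(abc_basis, "A")
    with pytest.raises(ValueError):
        op.apply_to_coefficients(np.ones(4))


def test_large_basis_is_matrix_free():
    basis = build_basis([f"w{j}" for j in range(13)])
    op = production_operator(basis, "w3")
    with pytest.raises(ValueError):
        _ = op.matrix
    state = uniform_state(basis)
    out = op.apply(state)
    assert out.norm_squared() == pytest.approx(1.0, abs=1e-9)
    eig = op.spectrum()
    assert eig.size == 2**13
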