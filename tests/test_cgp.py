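"""CGP genome decode/evaluate, mutation, evolution and expression export.

The reference interpreter here walks the *entire* node grid in column
order, independently of the package's active-node pruning, and serves as
the oracle for decode/evaluate correctness.
"""

import math

import numpy as np
import pytest

from cellmot import (
    EvolutionParams,
    FunctionSet,
    Genome,
    decode,
    evaluate,
    evaluate_expression,
    evolve,
    fitness,
    mutate,
    random_genome,
    to_expression,
)
from cellmot.cgp import VALUE_CLIP, evaluate_matrix
from cellmot.simulate import FEATURE_NAMES, FeatureTableConfig, generate_feature_table

FS = FunctionSet()
FIDX = {name: i for i, name in enumerate(FS.names)}


def make_genome(n_inputs, node_genes, output_gene, n_columns=None):
    g = Genome(n_inputs=n_inputs, n_columns=n_columns or len(node_genes))
    g.node_genes = [list(genes) for genes in node_genes]
    g.output_gene = output_gene
    g.validate()
    return g


def full_graph_interpreter(genome, inputs):
    """Oracle: evaluate every node left to right, then read the output."""
    clip = lambda v: min(max(v, -VALUE_CLIP), VALUE_CLIP)
    truth = lambda v: v > 0
    vals = list(map(float, inputs))
    for fidx, ia, ib in genome.node_genes:
        name = genome.functions.names[fidx]
        a = vals[ia] if genome.functions.arity(fidx) >= 1 else 0.0
        b = vals[ib] if genome.functions.arity(fidx) >= 2 else 0.0
        if name == "ADD":
            v = a + b
        elif name == "SUB":
            v = a - b
        elif name == "MUL":
            v = a * b
        elif name == "DIV":
            v = 1.0 if b == 0 else a / b
        elif name == "SQR":
            v = a * a
        elif name == "SQRT":
            v = math.sqrt(abs(a))
        elif name == "CUBE":
            v = a * a * a
        elif name == "CONST0":
            v = 0.0
        elif name == "CONST1":
            v = 1.0
        elif name == "AND":
            v = float(truth(a) and truth(b))
        elif name == "OR":
            v = float(truth(a) or truth(b))
        elif name == "NAND":
            v = float(not (truth(a) and truth(b)))
        elif name == "NOR":
            v = float(not (truth(a) or truth(b)))
        elif name == "NOT":
            v = float(not truth(a))
        vals.append(clip(v))
    return vals[genome.output_gene]


class TestDecode:
    def test_output_wired_to_input_has_no_active_nodes(self):
        g = make_genome(3, [[FIDX["ADD"], 0, 1]], output_gene=0)
        assert decode(g) == []

    def test_single_active_node(self):
        g = make_genome(2, [[FIDX["ADD"], 0, 1]], output_gene=2)
        assert decode(g) == [0]

    def test_matches_backward_reachability_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            g = random_genome(4, rng, n_columns=30)
            # independent reachability: breadth-first over referenced addresses
            reach, frontier = set(), {g.output_gene}
            while frontier:
                addr = frontier.pop()
                if addr < g.n_inputs or addr - g.n_inputs in reach:
                    continue
                node = addr - g.n_inputs
                reach.add(node)
                fidx, a, b = g.node_genes[node]
                arity = g.functions.arity(fidx)
                frontier |= {a} if arity == 1 else {a, b} if arity == 2 else set()
            assert decode(g) == sorted(reach)

    def test_invalid_forward_reference_rejected(self):
        with pytest.raises(ValueError):
            make_genome(2, [[FIDX["ADD"], 3, 0]], output_gene=2)


class TestEvaluate:
    def test_identity_genome(self):
        g = make_genome(3, [[FIDX["ADD"], 0, 1]], output_gene=0)
        assert evaluate(g, [7.5, 1.0, 2.0]) == 7.5

    def test_protected_division_by_zero(self):
        g = make_genome(2, [[FIDX["DIV"], 0, 1]], output_gene=2)
        assert evaluate(g, [5.0, 0.0]) == 1.0
        assert evaluate(g, [5.0, 2.0]) == 2.5

    def test_nand_with_positive_negative(self):
        g = make_genome(2, [[FIDX["NAND"], 0, 1]], output_gene=2)
        assert evaluate(g, [2.0, -1.0]) == 1.0
        assert evaluate(g, [2.0, 3.0]) == 0.0

    def test_sqrt_of_negative_uses_absolute_value(self):
        g = make_genome(1, [[FIDX["SQRT"], 0, 0]], output_gene=1)
        assert evaluate(g, [-9.0]) == 3.0

    def test_agrees_with_full_graph_interpreter(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            g = random_genome(10, rng, n_columns=70)
            X = rng.uniform(-2, 2, (10, 10))
            got = evaluate_matrix(g, X)
            want = [full_graph_interpreter(g, row) for row in X]
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_total_on_extreme_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            g = random_genome(4, rng, n_columns=70)
            out = evaluate(g, [1e90, -1e90, 1e-90, 0.0])
            assert math.isfinite(out)

    def test_rejects_non_finite_inputs(self):
        g = make_genome(2, [[FIDX["ADD"], 0, 1]], output_gene=2)
        with pytest.raises(ValueError):
            evaluate(g, [1.0, math.inf])

    def test_unused_inputs_never_affect_output(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            g = random_genome(6, rng, n_columns=40)
            _expr, used = to_expression(g, [f"x{i}" for i in range(6)])
            x = rng.uniform(-1, 1, 6)
            base = evaluate(g, x)
            for i in set(range(6)) - used:
                x2 = x.copy()
                x2[i] = rng.uniform(-100, 100)
                assert evaluate(g, x2) == base


class TestMutate:
    params = EvolutionParams()

    def test_rate_zero_is_identity(self):
        rng = np.random.default_rng(0)
        g = random_genome(5, rng)
        m = mutate(g, EvolutionParams(mutation_rate=0.0), rng)
        assert m.node_genes == g.node_genes and m.output_gene == g.output_gene

    def test_rate_one_still_valid_and_leaves_parent_unchanged(self):
        rng = np.random.default_rng(1)
        g = random_genome(5, rng)
        snapshot = [list(x) for x in g.node_genes]
        m = mutate(g, EvolutionParams(mutation_rate=1.0), rng)
        m.validate()
        assert g.node_genes == snapshot  # parent untouched

    def test_observed_change_fraction_matches_resampling_expectation(self):
        """At rate p each gene resamples uniformly over its range r, so the
        expected changed fraction per gene is p * (1 - 1/r)."""
        rng = np.random.default_rng(7)
        g = random_genome(10, rng, n_columns=70)
        p = 0.01
        n_trials = 10_000
        # per-gene expected change probability
        expectations, changes = [], 0
        gene_ranges = []
        for c in range(g.n_columns):
            gene_ranges.append(len(g.functions))
            gene_ranges += [len(g.source_choices(c))] * 2
        gene_ranges.append(g.n_inputs + g.n_columns)
        expected = p * np.mean([1 - 1 / r for r in gene_ranges])
        n_genes = len(gene_ranges)
        for _ in range(n_trials):
            m = mutate(g, EvolutionParams(mutation_rate=p), rng)
            diff = sum(mg != gg for mrow, grow in zip(m.node_genes, g.node_genes)
                       for mg, gg in zip(mrow, grow))
            diff += m.output_gene != g.output_gene
            changes += diff
        frac = changes / (n_trials * n_genes)
        se = math.sqrt(expected * (1 - expected) / (n_trials * n_genes))
        assert abs(frac - expected) < 3 * se


class TestFitness:
    def test_constant_one_on_all_positive(self):
        g = make_genome(2, [[FIDX["CONST1"], 0, 0]], output_gene=2)
        X = np.zeros((6, 2))
        assert fitness(g, X, ["a"] * 6, positive_label="a") == 1.0

    def test_constant_one_on_balanced(self):
        g = make_genome(2, [[FIDX["CONST1"], 0, 0]], output_gene=2)
        X = np.zeros((6, 2))
        assert fitness(g, X, ["a"] * 3 + ["b"] * 3, positive_label="a") == 0.5

    def test_identity_threshold_classifier(self):
        g = make_genome(2, [[FIDX["ADD"], 0, 0]], output_gene=0)
        X = np.array([[1.0, 0], [-1.0, 0], [2.0, 0], [-0.5, 0]])
        y = ["pos", "neg", "pos", "neg"]
        assert fitness(g, X, y, positive_label="pos") == 1.0


class TestEvolve:
    def separable(self, seed=0):
        cfg = FeatureTableConfig(class_sds=((0.0,) * 10, (0.0,) * 10), seed=seed)
        df = generate_feature_table(cfg)
        return df[FEATURE_NAMES].to_numpy(float), df["label"].to_numpy()

    def test_reaches_perfect_accuracy_on_separable_data(self):
        X, y = self.separable()
        clf, trace = evolve(X, y, EvolutionParams(seed=1), feature_names=FEATURE_NAMES)
        assert trace[-1] == 1.0
        assert clf.accuracy(X, y) == 1.0

    def test_single_class_dataset_trivially_perfect(self):
        X = np.random.default_rng(0).uniform(0, 1, (8, 3))
        clf, trace = evolve(X, ["only"] * 8, EvolutionParams(seed=2, generations=200))
        assert trace[-1] == 1.0

    def test_trace_is_monotonically_non_decreasing(self):
        X, y = self.separable(3)
        # make it hard enough to take some generations
        X = X + np.random.default_rng(4).normal(0, 0.8, X.shape)
        _clf, trace = evolve(X, y, EvolutionParams(seed=5, generations=300))
        assert all(a <= b for a, b in zip(trace, trace[1:]))

    def test_reproducible_given_seed(self):
        X, y = self.separable(6)
        c1, t1 = evolve(X, y, EvolutionParams(seed=9))
        c2, t2 = evolve(X, y, EvolutionParams(seed=9))
        assert t1 == t2
        assert c1.genome.node_genes == c2.genome.node_genes
        assert c1.genome.output_gene == c2.genome.output_gene

    def test_classifier_json_round_trip(self):
        from cellmot.cgp import Classifier

        X, y = self.separable(7)
        clf, _ = evolve(X, y, EvolutionParams(seed=11), feature_names=FEATURE_NAMES)
        clf2 = Classifier.from_json(clf.to_json())
        np.testing.assert_array_equal(clf.predict(X), clf2.predict(X))


class TestExpression:
    def test_identity_genome(self):
        g = make_genome(10, [[FIDX["ADD"], 0, 1]], output_gene=0)
        expr, used = to_expression(g, FEATURE_NAMES)
        assert expr == "avg_migration_speed"
        assert used == {0}

    def test_nested_arithmetic(self):
        g = make_genome(10, [
            [FIDX["MUL"], 1, 2],            # node addr 10: in1 * in2
            [FIDX["ADD"], 0, 10],           # node addr 11: in0 + node10
        ], output_gene=11)
        expr, used = to_expression(g, FEATURE_NAMES)
        assert expr == "(avg_migration_speed + (post_contact_speed * in_contact_speed))"
        assert used == {0, 1, 2}

    def test_round_trip_random_genomes(self):
        rng = np.random.default_rng(23)
        names = [f"x{i}" for i in range(8)]
        for _ in range(30):
            g = random_genome(8, rng, n_columns=40)
            expr, _used = to_expression(g, names)
            for _ in range(5):
                x = rng.uniform(-3, 3, 8)
                want = evaluate(g, x)
                got = evaluate_expression(expr, dict(zip(names, x)))
                assert got == pytest.approx(want, abs=1e-9)
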