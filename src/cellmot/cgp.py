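"""Cartesian Genetic Programming classifier over motility features.

A genome encodes a fixed, feed-forward directed graph: a single row of
``n_columns`` function nodes, each holding a function gene and two input
genes that may reference the program inputs or any strictly earlier node
(``levels_back`` = ``n_columns`` by default, i.e. full connectivity), plus
one output gene.  Only the nodes reachable backwards from the output are
*active*; the rest are silent but remain in the genome and can be revived
by mutation (neutral drift).

The function set combines arithmetic operators (+, -, *, /, SQR, SQRT,
CUBE), the constants 0 and 1, and logical operators (AND, OR, NAND, NOR,
NOT).  All functions are *protected* so that any genome maps finite inputs
to a finite output: division by zero yields 1, SQRT takes the root of the
absolute value, logical operators read an operand as true iff it is
strictly positive and emit 1.0/0.0, and every node's result is clamped to
+-1e100 so arithmetic chains cannot overflow to infinity.

Training uses a (1 + lambda) evolution strategy with point mutation: each
generation keeps the fittest individual — preferring an offspring over the
parent on ties, which enables neutral drift — and refills the population
with mutated clones.  Fitness is training-set classification accuracy,
where a row is called positive iff the network output on min-max
normalised features exceeds the decision threshold (0 by default).
The evolved network decodes to an ordinary mathematical expression over
the feature names, exposing which features drive the classification.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FunctionSet",
    "DEFAULT_FUNCTIONS",
    "Genome",
    "EvolutionParams",
    "Classifier",
    "random_genome",
    "decode",
    "evaluate",
    "evaluate_matrix",
    "mutate",
    "fitness",
    "evolve",
    "to_expression",
    "evaluate_expression",
]

#: Per-node output clamp keeping every evaluation finite.
VALUE_CLIP = 1e100


def _clip(v):
    return np.clip(v, -VALUE_CLIP, VALUE_CLIP)


def _truth(v):
    return np.asarray(v) > 0


# name -> (arity, vectorised semantics)
_SEMANTICS = {
    "ADD": (2, lambda a, b: a + b),
    "SUB": (2, lambda a, b: a - b),
    "MUL": (2, lambda a, b: a * b),
    "DIV": (2, lambda a, b: np.where(b == 0, 1.0, a / np.where(b == 0, 1.0, b))),
    "SQR": (1, lambda a, b: a * a),
    "SQRT": (1, lambda a, b: np.sqrt(np.abs(a))),
    "CUBE": (1, lambda a, b: a * a * a),
    "CONST0": (0, lambda a, b: np.zeros_like(a)),
    "CONST1": (0, lambda a, b: np.ones_like(a)),
    "AND": (2, lambda a, b: (_truth(a) & _truth(b)).astype(float)),
    "OR": (2, lambda a, b: (_truth(a) | _truth(b)).astype(float)),
    "NAND": (2, lambda a, b: (~(_truth(a) & _truth(b))).astype(float)),
    "NOR": (2, lambda a, b: (~(_truth(a) | _truth(b))).astype(float)),
    "NOT": (1, lambda a, b: (~_truth(a)).astype(float)),
}


@dataclass(frozen=True)
class FunctionSet:
    """Ordered list of primitive functions available to the nodes."""

    names: tuple[str, ...] = (
        "ADD", "SUB", "MUL", "DIV", "SQR", "SQRT", "CUBE",
        "CONST0", "CONST1", "AND", "OR", "NAND", "NOR", "NOT",
    )

    def __post_init__(self):
        unknown = [n for n in self.names if n not in _SEMANTICS]
        if unknown:
            raise ValueError(f"unknown functions: {unknown}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("function names must be unique")

    def arity(self, idx: int) -> int:
        return _SEMANTICS[self.names[idx]][0]

    def apply(self, idx: int, a, b):
        return _clip(_SEMANTICS[self.names[idx]][1](a, b))

    def __len__(self) -> int:
        return len(self.names)


DEFAULT_FUNCTIONS = FunctionSet()

MAX_ARITY = 2


@dataclass
class Genome:
    """A CGP chromosome: single-row feed-forward graph of function nodes.

    Node ``i`` has address ``n_inputs + i``; program inputs occupy
    addresses ``0 .. n_inputs-1``.  Each node carries a function gene and
    ``MAX_ARITY`` input genes; unary functions read the first operand only
    and constants read none (unused genes stay in the genome, silently
    inactive).  ``output_gene`` is the address whose value the program
    returns.
    """

    n_inputs: int
    n_columns: int = 70
    n_rows: int = 1
    levels_back: int | None = None
    functions: FunctionSet = field(default_factory=FunctionSet)
    node_genes: list[list[int]] = field(default_factory=list)  # [fidx, in1, in2]
    output_gene: int = 0

    def __post_init__(self):
        if self.levels_back is None:
            self.levels_back = self.n_columns
        if self.n_rows != 1:
            raise ValueError("only single-row genomes are supported")
        if self.node_genes:
            self.validate()

    def source_choices(self, column: int) -> list[int]:
        """Valid source addresses for a node in ``column``.

        Program inputs are always allowed; earlier nodes only within
        ``levels_back`` columns.
        """
        lo = self.n_inputs + max(0, column - self.levels_back)
        hi = self.n_inputs + column
        return list(range(self.n_inputs)) + list(range(lo, hi))

    def _valid_source(self, column: int, addr: int) -> bool:
        if 0 <= addr < self.n_inputs:
            return True
        return (self.n_inputs + max(0, column - self.levels_back)
                <= addr < self.n_inputs + column)

    def validate(self) -> None:
        if len(self.node_genes) != self.n_columns:
            raise ValueError("node_genes length must equal n_columns")
        for c, genes in enumerate(self.node_genes):
            fidx, *ins = genes
            if not 0 <= fidx < len(self.functions):
                raise ValueError(f"node {c}: invalid function index {fidx}")
            if len(ins) != MAX_ARITY:
                raise ValueError(f"node {c}: expected {MAX_ARITY} input genes")
            for a in ins:
                if not self._valid_source(c, a):
                    raise ValueError(f"node {c}: input address {a} violates feed-forward order")
        if not 0 <= self.output_gene < self.n_inputs + self.n_columns:
            raise ValueError("invalid output gene")

    def copy(self) -> "Genome":
        return Genome(
            n_inputs=self.n_inputs, n_columns=self.n_columns, n_rows=self.n_rows,
            levels_back=self.levels_back, functions=self.functions,
            node_genes=[list(g) for g in self.node_genes],
            output_gene=self.output_gene,
        )

    def to_json(self) -> str:
        return json.dumps({
            "n_inputs": self.n_inputs,
            "n_columns": self.n_columns,
            "n_rows": self.n_rows,
            "levels_back": self.levels_back,
            "function_set": list(self.functions.names),
            "node_genes": self.node_genes,
            "output_gene": self.output_gene,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Genome":
        d = json.loads(text)
        return cls(
            n_inputs=d["n_inputs"], n_columns=d["n_columns"], n_rows=d["n_rows"],
            levels_back=d["levels_back"],
            functions=FunctionSet(tuple(d["function_set"])),
            node_genes=[list(g) for g in d["node_genes"]],
            output_gene=d["output_gene"],
        )


def random_genome(
    n_inputs: int,
    rng: np.random.Generator,
    n_columns: int = 70,
    levels_back: int | None = None,
    functions: FunctionSet = DEFAULT_FUNCTIONS,
) -> Genome:
    """Uniformly random valid genome."""
    g = Genome(n_inputs=n_inputs, n_columns=n_columns, levels_back=levels_back,
               functions=functions)
    for c in range(n_columns):
        choices = g.source_choices(c)
        genes = [int(rng.integers(len(functions)))]
        genes += [int(choices[rng.integers(len(choices))]) for _ in range(MAX_ARITY)]
        g.node_genes.append(genes)
    g.output_gene = int(rng.integers(n_inputs + n_columns))
    g.validate()
    return g


def decode(genome: Genome) -> list[int]:
    """Active node indices (0-based column order) reachable from the output."""
    genome.validate()
    active: set[int] = set()
    stack = [genome.output_gene]
    while stack:
        addr = stack.pop()
        if addr < genome.n_inputs:
            continue
        node = addr - genome.n_inputs
        if node in active:
            continue
        active.add(node)
        fidx, a, b = genome.node_genes[node]
        arity = genome.functions.arity(fidx)
        if arity >= 1:
            stack.append(a)
        if arity >= 2:
            stack.append(b)
    return sorted(active)


def evaluate_matrix(genome: Genome, X: np.ndarray) -> np.ndarray:
    """Evaluate the genome on every row of ``X``; returns shape (n,).

    Only active nodes are computed; all operators are protected and every
    node output clamped, so the result is finite for finite inputs.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != genome.n_inputs:
        raise ValueError(f"expected {genome.n_inputs} inputs, got {X.shape[1]}")
    if not np.isfinite(X).all():
        raise ValueError("non-finite inputs rejected")
    values: dict[int, np.ndarray] = {i: X[:, i] for i in range(genome.n_inputs)}
    for node in decode(genome):
        fidx, ia, ib = genome.node_genes[node]
        arity = genome.functions.arity(fidx)
        a = values[ia] if arity >= 1 else np.zeros(X.shape[0])
        b = values[ib] if arity >= 2 else np.zeros(X.shape[0])
        values[genome.n_inputs + node] = genome.functions.apply(fidx, a, b)
    return np.asarray(values[genome.output_gene], dtype=float)


def evaluate(genome: Genome, inputs) -> float:
    """Evaluate the genome on a single input vector."""
    return float(evaluate_matrix(genome, np.asarray(inputs, dtype=float))[0])


@dataclass(frozen=True)
class EvolutionParams:
    """(1 + lambda) strategy configuration.

    Defaults: population 10 (one parent + nine mutated clones), point
    mutation at 1% per gene, at most 10,000 generations, stopping early on
    perfect training accuracy.
    """

    population_size: int = 10
    mutation_rate: float = 0.01
    generations: int = 10_000
    seed: int = 0
    n_columns: int = 70
    levels_back: int | None = None
    functions: FunctionSet = field(default_factory=FunctionSet)
    prefer_offspring_on_tie: bool = True

    def validate(self) -> None:
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


def mutate(genome: Genome, params: EvolutionParams, rng: np.random.Generator) -> Genome:
    """Point mutation: each gene independently resampled with probability
    ``mutation_rate``, uniformly over its valid range (the current value
    included).  The input genome is left unchanged."""
    params.validate()
    g = genome.copy()
    p = params.mutation_rate
    hit = rng.random(g.n_columns * (1 + MAX_ARITY) + 1) < p
    i = 0
    for c in range(g.n_columns):
        if hit[i]:
            g.node_genes[c][0] = int(rng.integers(len(g.functions)))
        i += 1
        for k in range(1, 1 + MAX_ARITY):
            if hit[i]:
                src = g.source_choices(c)
                if src:
                    g.node_genes[c][k] = int(src[rng.integers(len(src))])
            i += 1
    if hit[i]:
        g.output_gene = int(rng.integers(g.n_inputs + g.n_columns))
    g.validate()
    return g


def _normalize(X: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; constant features map to 0."""
    span = hi - lo
    out = np.zeros_like(X, dtype=float)
    nz = span > 0
    out[:, nz] = (X[:, nz] - lo[nz]) / span[nz]
    return out


@dataclass
class Classifier:
    """An evolved genome plus the training-set normalisation and decision rule."""

    genome: Genome
    feature_min: np.ndarray
    feature_max: np.ndarray
    positive_label: object
    negative_label: object
    decision_threshold: float = 0.0
    feature_names: list[str] | None = None

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        Xn = _normalize(np.asarray(X, dtype=float), self.feature_min, self.feature_max)
        return evaluate_matrix(self.genome, Xn)

    def predict(self, X: np.ndarray) -> np.ndarray:
        pos = self.decision_values(X) > self.decision_threshold
        return np.where(pos, self.positive_label, self.negative_label)

    def accuracy(self, X: np.ndarray, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def expression(self) -> tuple[str, set[int]]:
        names = self.feature_names or [f"x{i}" for i in range(self.genome.n_inputs)]
        return to_expression(self.genome, names)

    def to_json(self) -> str:
        expr, used = self.expression()
        return json.dumps({
            "genome": json.loads(self.genome.to_json()),
            "feature_min": list(map(float, self.feature_min)),
            "feature_max": list(map(float, self.feature_max)),
            "positive_label": self.positive_label,
            "negative_label": self.negative_label,
            "decision_threshold": self.decision_threshold,
            "feature_names": self.feature_names,
            "expression": expr,
            "used_inputs": sorted(used),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Classifier":
        d = json.loads(text)
        return cls(
            genome=Genome.from_json(json.dumps(d["genome"])),
            feature_min=np.asarray(d["feature_min"], dtype=float),
            feature_max=np.asarray(d["feature_max"], dtype=float),
            positive_label=d["positive_label"],
            negative_label=d["negative_label"],
            decision_threshold=d["decision_threshold"],
            feature_names=d["feature_names"],
        )


def fitness(
    genome: Genome,
    X: np.ndarray,
    y,
    positive_label,
    threshold: float = 0.0,
) -> float:
    """Training accuracy of a genome on (already normalised) features."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty dataset")
    pred_pos = evaluate_matrix(genome, X) > threshold
    actual_pos = np.asarray(y) == positive_label
    return float(np.mean(pred_pos == actual_pos))


def evolve(
    X: np.ndarray,
    y,
    params: EvolutionParams | None = None,
    positive_label=None,
    feature_names: list[str] | None = None,
) -> tuple[Classifier, list[float]]:
    """Evolve a classifier with a (1 + lambda) strategy.

    Returns the classifier built from the best genome found and the
    per-generation best-fitness trace (monotonically non-decreasing).
    Deterministic given ``params.seed``.  Evolution stops at perfect
    training accuracy or after ``params.generations`` generations.
    """
    params = params or EvolutionParams()
    params.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = sorted(set(y.tolist()), key=str)
    if positive_label is None:
        positive_label = labels[-1]
    negative_label = next((l for l in labels if l != positive_label), positive_label)
    lo, hi = X.min(axis=0), X.max(axis=0)
    Xn = _normalize(X, lo, hi)
    rng = np.random.default_rng(params.seed)

    population = [random_genome(X.shape[1], rng, params.n_columns,
                                params.levels_back, params.functions)
                  for _ in range(params.population_size)]
    fits = [fitness(g, Xn, y, positive_label) for g in population]
    best_i = int(np.argmax(fits))
    parent, parent_fit = population[best_i], fits[best_i]
    trace = [parent_fit]

    for _gen in range(params.generations):
        if parent_fit >= 1.0:
            break
        best_child, best_child_fit = None, -1.0
        for _ in range(params.population_size - 1):
            child = mutate(parent, params, rng)
            f = fitness(child, Xn, y, positive_label)
            if f > best_child_fit:
                best_child, best_child_fit = child, f
        accept = (best_child_fit >= parent_fit if params.prefer_offspring_on_tie
                  else best_child_fit > parent_fit)
        if accept:
            parent, parent_fit = best_child, best_child_fit
        trace.append(parent_fit)

    clf = Classifier(
        genome=parent, feature_min=lo, feature_max=hi,
        positive_label=positive_label, negative_label=negative_label,
        feature_names=feature_names,
    )
    return clf, trace


# --- expression export -------------------------------------------------------

_UNARY_RENDER = {"SQR": "sqr", "SQRT": "sqrt", "CUBE": "cube", "NOT": "NOT"}
_BINARY_INFIX = {"ADD": "+", "SUB": "-", "MUL": "*"}
_BINARY_CALL = {"DIV": "pdiv", "AND": "AND", "OR": "OR", "NAND": "NAND", "NOR": "NOR"}


def to_expression(genome: Genome, feature_names: list[str]) -> tuple[str, set[int]]:
    """Render the active network as a parenthesised infix expression.

    Protected operations appear as named helpers — ``pdiv(a, b)`` is
    division returning 1 when b = 0, ``sqrt`` takes the absolute value
    first, and the logical helpers use the strictly-positive truth
    convention.  Also returns the set of input indices the expression
    actually depends on.
    """
    genome.validate()
    if len(feature_names) < genome.n_inputs:
        raise ValueError("need a name for every input")
    used: set[int] = set()
    memo: dict[int, str] = {}

    def render(addr: int) -> str:
        if addr < genome.n_inputs:
            used.add(addr)
            return feature_names[addr]
        if addr in memo:
            return memo[addr]
        fidx, a, b = genome.node_genes[addr - genome.n_inputs]
        name = genome.functions.names[fidx]
        if name == "CONST0":
            s = "0"
        elif name == "CONST1":
            s = "1"
        elif name in _UNARY_RENDER:
            s = f"{_UNARY_RENDER[name]}({render(a)})"
        elif name in _BINARY_INFIX:
            s = f"({render(a)} {_BINARY_INFIX[name]} {render(b)})"
        else:
            s = f"{_BINARY_CALL[name]}({render(a)}, {render(b)})"
        memo[addr] = s
        return s

    return render(genome.output_gene), used


class _Protected(float):
    """Float whose arithmetic mirrors the protected, clamped node semantics,
    so exported expressions re-evaluate exactly like the genome."""

    def _new(self, v):
        return _Protected(float(np.clip(v, -VALUE_CLIP, VALUE_CLIP)))

    def __add__(self, o): return self._new(float(self) + float(o))
    __radd__ = __add__

    def __sub__(self, o): return self._new(float(self) - float(o))

    def __rsub__(self, o): return self._new(float(o) - float(self))

    def __mul__(self, o): return self._new(float(self) * float(o))
    __rmul__ = __mul__


def evaluate_expression(expr: str, feature_values: dict[str, float]) -> float:
    """Evaluate an exported expression string at given feature values.

    Provides the protected helpers (``pdiv``, ``sqr``, ``sqrt``, ``cube``
    and the logical operators) with exactly the genome's semantics.
    """
    def wrap(f):
        return lambda *args: _Protected(
            float(np.clip(f(*[float(a) for a in args]), -VALUE_CLIP, VALUE_CLIP)))

    ns = {
        "pdiv": wrap(lambda a, b: 1.0 if b == 0 else a / b),
        "sqr": wrap(lambda a: a * a),
        "sqrt": wrap(lambda a: math.sqrt(abs(a))),
        "cube": wrap(lambda a: a * a * a),
        "AND": wrap(lambda a, b: float(a > 0 and b > 0)),
        "OR": wrap(lambda a, b: float(a > 0 or b > 0)),
        "NAND": wrap(lambda a, b: float(not (a > 0 and b > 0))),
        "NOR": wrap(lambda a, b: float(not (a > 0 or b > 0))),
        "NOT": wrap(lambda a: float(not a > 0)),
        "__builtins__": {},
    }
    ns.update({k: _Protected(v) for k, v in feature_values.items()})
    return float(eval(expr, ns))  # noqa: S307 - expressions are produced by to_expression
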