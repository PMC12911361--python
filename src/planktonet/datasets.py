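"""Bundled example dataset.

A small synthetic three-year survey (60 samples, ~150 ASVs) generated by
:func:`planktonet.simulate.generate_community` with the recorded seed, shipped
as plain TSV/JSON so every CLI subcommand and the documentation examples have
an input that needs no generation step. ``load_example()`` reads it;
``regenerate_example()`` rebuilds it bit-for-bit from the recorded seed.
"""

from __future__ import annotations

from importlib.resources import files

from planktonet import simulate

#: Seeds used to build the committed fixture; regeneration must be bit-exact.
EXAMPLE_SEED = 20
EXAMPLE_TRAIT_SEED = 21

EXAMPLE_TRAIT_FRACTIONS = {"Archaeplastida": 0.45, "Dinoflagellata": 0.20,
                           "Haptophyta": 0.0}
EXAMPLE_TRAIT_RESIDUAL = 0.35


def example_path():
    return files("planktonet.data").joinpath("example")


def load_example() -> simulate.SyntheticDataset:
    """Load the committed example survey fixture."""
    return simulate.load_fixture(example_path())


def regenerate_example() -> simulate.SyntheticDataset:
    """Rebuild the example dataset from its recorded seeds (determinism check)."""
    ds = simulate.generate_community(seed=EXAMPLE_SEED)
    simulate.generate_traits(ds, EXAMPLE_TRAIT_FRACTIONS, EXAMPLE_TRAIT_RESIDUAL,
                             seed=EXAMPLE_TRAIT_SEED)
    return ds
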