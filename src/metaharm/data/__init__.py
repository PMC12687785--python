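"""Packaged synthetic fixtures: an ancestry-category ontology snapshot and a
small demo harmonization project.  All ids in these files are synthetic
except the 'ancestry category' CURIE itself."""

from importlib import resources


def _path(*parts) -> str:
    return str(resources.files(__name__).joinpath(*parts))


def ancestry_fixture_path() -> str:
    """Synthetic ancestry-category ontology snapshot (OBO)."""
    return _path("ancestry_synthetic.obo")


def load_ancestry_fixture():
    """Load the synthetic ancestry ontology as an :class:`OntologyGraph`."""
    from ..ontology import read_obo
    return read_obo(ancestry_fixture_path())


def demo_config_path() -> str:
    """Config file of the packaged demo harmonization project."""
    return _path("demo", "config.yaml")
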