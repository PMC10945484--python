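"""dibkit: droplet-interface-bilayer permeability, DSC endotherm, and Raman
packing-order analysis with matched synthetic-data generators."""

__version__ = "0.1.0"

from . import droplet_geometry, dsc, permeability, raman  # noqa: F401

__all__ = [
    "__version__",
    "droplet_geometry",
    "dsc",
    "permeability",
    "raman",
    "synthetic_data",
    "io",
    "report",
]


def __getattr__(name):
    # synthetic_data and report import the analysis modules; lazy import
    # keeps `import dibkit` cheap and avoids cycles
    if name in ("synthetic_data", "io", "report"):
        import importlib

        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
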