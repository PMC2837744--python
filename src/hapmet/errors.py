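"""Exception hierarchy shared across the package."""


class HapmetError(Exception):
    """Base class for all package-specific errors."""


class InputError(HapmetError, ValueError):
    """Malformed or invalid user input (files, tables, parameters)."""


class AlignmentError(InputError):
    """Sequence alignment violates an invariant (lengths, ids, alphabet)."""


class TreeError(InputError):
    """A tree or tree set violates an invariant."""


class NetworkError(HapmetError):
    """Haplotype-network construction or query failure."""


class ModelError(HapmetError):
    """Continuous trait model fitting / sampling failure."""
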