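"""Exception hierarchy shared across the pipeline stages."""


class NetstabError(Exception):
    """Base class for all package errors."""


class ConfigError(NetstabError):
    """Invalid configuration (bad parameter value, inconsistent fields)."""


class ParameterError(NetstabError):
    """A numeric parameter is outside its valid domain (e.g. above Nyquist)."""


class DataError(NetstabError):
    """Input data violate a structural precondition."""


class GraphDisconnectedError(NetstabError):
    """A path-based graph metric was requested on a disconnected graph.

    Characteristic path length is undefined when some node pairs are
    unreachable; callers may re-run with ``on_disconnected="largest"`` to
    obtain the largest-connected-component value (flagged with a warning).
    """
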