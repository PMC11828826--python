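"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A spec/config object violates one of its invariants."""


class DecompositionError(RuntimeError):
    """Signal decomposition (ICA or VMD) failed on degenerate input."""


class NoLabeledWindowsError(RuntimeError):
    """Feature extraction found no window carrying a single emotion label."""
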