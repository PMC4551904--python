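class RaxError(ValueError):
    """Validation or contract violation in rax2 inputs or intermediate state.

    The CLI maps this to exit code 2.
    """
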