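a
an
and
are
as
at
be
but
by
for
from
has
have
he
her
his
i
in
is
it
its
my
no
not
of
on
or
she
so
that
the
their
then
they
this
to
was
we
were
with
you
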