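word,category
of,IGNORABLE
the,IGNORABLE
a,IGNORABLE
an,IGNORABLE
and,IGNORABLE
or,IGNORABLE
in,IGNORABLE
on,IGNORABLE
at,IGNORABLE
to,IGNORABLE
with,IGNORABLE
by,IGNORABLE
for,IGNORABLE
other,IGNORABLE
unspecified,IGNORABLE
this,IGNORABLE
that,IGNORABLE
is,IGNORABLE
was,IGNORABLE
has,IGNORABLE
had,IGNORABLE
while,IGNORABLE
right,OPTIONAL
left,OPTIONAL
acute,OPTIONAL
chronic,OPTIONAL
heart,OPTIONAL
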