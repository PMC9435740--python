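>g0001t1_prot
MVTMITTSPKSDSRPRHGICVVPIRVSLSALLFVDRSFSKFNTVIEESNYQTTIKVWPFK
LCSVATRPLITSSCGMWYHPWLKDFDMLDTHGAYKHGQDLPFS
>g0001t2_prot
MVTMITTSPKSDSRPRHGICVVPIRVSLSALLFVDRPLITSSCGMWYHPWLKDFDMLDTH
GAYKHGQDLPFS
>g0001tG_prot
MVTMITTSPKSDSRPRHGICVVPIRVSLSALLFVDRSFSKFNTVIEESNYQTTIKVWPFK
LCSVATRVERTLREHPGSMLMSPLITSSCGMWYHPWLKDFDMLDTHGAYKHGQDLPFS
>g0002t1_prot
MRSVRLVGIMDAAELPLRAIHKLLAPNLLSRATYIGLCTPNYGNFSYLGLNRRHIPLLSL
ALSHQPARSEVIRQSELPRLEAVRGSRLARLPRPIAVKL
>g0002t2_prot
MRSVRLVGIMDAAELPLRAIHKLLAPNLLSRATYIGLCTPNYGNFSYLGLNRRHIPLLSL
ALSHQPARSEVIRQWLPCSYIRIHLKS
>g0004t1_prot
MPALRFRLSPKQYRRCGQVRVFVMKLRGGDMNAECTIARSYVMSVQHTSELSGLIVLMRG
DSVRYRAPNRAVRKTATPIYASEYPSASRVCLTAKFCLIKKCVFRCFSSDAQVL
>g0004t2_prot
MPALRFRLSPKQYRRCGQVRVFVMKLRGGDMNAECTIARSYVMSVQHTSELSGLIVLMRG
DSVRYRAPNRARCFSSDAQVL
>g0004tX_prot
MSETGSLNEYAKRLHRFTLQSIPAPQEFVSRRNSASSRSVFSAASPVTLRYCDPQRSRTY
LRRLNSMRARDLASPCRTLISHVWFTLTTIRNREFYMTQCRTQEPTVR
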