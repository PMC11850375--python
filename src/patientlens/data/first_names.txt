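Alice
Amelia
Anna
Arthur
Ben
Carla
Charlotte
Clara
Daniel
David
Diana
Edward
Elena
Emily
Emma
Ethan
Fiona
Frank
George
Grace
Hannah
Harry
Helen
Henry
Isabel
Jack
James
Jane
John
Julia
Karen
Laura
Leo
Liam
Lucy
Maria
Mark
Martha
Mary
Michael
Nina
Noah
Oliver
Olivia
Oscar
Paul
Peter
Rachel
Robert
Rosa
Ruth
Sam
Sarah
Sophia
Susan
Thomas
Tom
Victor
Walter
William
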